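"""End-to-end orchestration: island + attachment-site report, multi-island
comparison (segmentation / variants / Ka-Ks), and the multi-rate dating
table.  Outputs are plain TSV files with a provenance header comment."""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import att_analysis, island_scanner, phylodating, segmentation, selection
from .seqio import GenomeRecord, MultipleAlignment, read_tree, to_report

log = logging.getLogger("islandmob")


@dataclass
class RunConfig:
    genomes: list[tuple[str, str]] = field(default_factory=list)  # (fasta, gff3)
    msa_path: str | None = None
    tree_path: str | None = None
    rates_path: str | None = None
    out_dir: str = "islandmob_out"
    tag_length: int = 20
    scan_window: int = 100_000
    max_mismatches: int = 3
    flank_width: int = 84
    flank_upstream: int = 34
    consensus_threshold: float = 0.75
    motif_length: int = 15
    identity_window: int = 14
    leader_bp: int = 129
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: str, config: RunConfig) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# islandmob config={config.digest()}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------

def scan_genome(genome: GenomeRecord, config: RunConfig,
                reference_ssrA: str | None = None):
    """Locate ssrA, scan repeats, delineate islands and detect modules for
    one genome; returns (genome, locus, hits, islands) in normalized
    orientation."""
    locus = island_scanner.locate_ssrA(genome, reference_ssrA,
                                       tag_length=config.tag_length)
    genome, locus = island_scanner.normalize_orientation(genome, locus)
    tag = island_scanner.extract_tag(locus, config.tag_length)
    hits = island_scanner.scan_direct_repeats(
        genome, locus, tag, config.scan_window, config.max_mismatches)
    islands = island_scanner.delineate_islands(genome, locus, hits)
    for isl in islands:
        module = island_scanner.detect_integration_module(genome, isl)
        if module is not None:
            isl.has_integration_module = True
            isl.module = module
            island_scanner.locate_module_trna(genome, isl, module)
    return genome, locus, hits, islands


def run_island_report(genomes: list[GenomeRecord], config: RunConfig,
                      reference_ssrA: str | None = None) -> dict:
    """Per-genome island tables plus the combined flank-alignment analysis
    (consensus, att motif, insertion site)."""
    rows, entries = [], []
    ssra_lengths = set()
    for genome in genomes:
        genome, locus, hits, islands = scan_genome(genome, config,
                                                   reference_ssrA)
        ssra_lengths.add(len(locus.sequence))
        entries.extend(att_analysis.flank_sources_from_scan(genome, locus, hits))
        for isl in islands:
            attL_1, attR_1 = to_report(isl.attL, isl.attR)
            module = isl.module
            rows.append({
                "genome": genome.id, "order_index": isl.order_index,
                "attL": attL_1, "attR": attR_1, "n_genes": len(isl.genes),
                "has_module": isl.has_integration_module,
                "module_roles": ",".join(module.gene_roles) if module else "",
                "trna_start": (to_report(*module.trna_locus)[0]
                               if module and module.trna_locus else ""),
            })
    islands_df = pd.DataFrame(rows)
    result = {"islands": islands_df, "flanks": None, "consensus": None,
              "motif": None, "insertion": None}
    dr_rows = sum(1 for _, s in entries if s.kind == "DR")
    if len(entries) >= 2:
        flanks = att_analysis.extract_flanks(
            entries, config.flank_width, config.flank_upstream,
            config.tag_length)
        result["flanks"] = flanks
        result["consensus"] = att_analysis.consensus(
            flanks, config.consensus_threshold)
        if dr_rows >= 3:
            result["motif"] = att_analysis.derive_att_motif(
                flanks, config.motif_length)
            result["insertion"] = att_analysis.infer_insertion_site(
                flanks, ssra_length=max(ssra_lengths))
    _write_tsv(islands_df, os.path.join(config.out_dir, "islands.tsv"), config)
    report = []
    if result["consensus"]:
        report.append(("consensus", result["consensus"].consensus))
    if result["motif"]:
        report.append(("att_motif", result["motif"].motif))
    if result["insertion"]:
        ins = result["insertion"]
        report.append(("insertion_after_ssrA_position", ins.five_prime_pos))
        report.append(("repeat_span", f"{ins.repeat_span[0]}-{ins.repeat_span[1]}"))
    _write_tsv(pd.DataFrame(report, columns=["key", "value"]),
               os.path.join(config.out_dir, "att_report.tsv"), config)
    return result


def run_vcr_compare(msa: MultipleAlignment, config: RunConfig,
                    cargo_interval: tuple[int, int] | None = None) -> dict:
    """Segment a multi-island alignment into integration vs cargo regions
    and run variant / Ka-Ks accounting on the cargo gene.

    ``cargo_interval`` gives the in-frame cargo CDS columns; the leader is
    its first ``config.leader_bp`` bp.
    """
    profile = segmentation.identity_profile(msa, config.identity_window)
    seg = segmentation.segment_two(msa, config.identity_window)
    variants = selection.variant_columns(msa)
    out = {"profile": profile, "segmentation": seg, "variants": variants,
           "kaks": None}
    seg_df = pd.DataFrame([{
        "boundary_column": (seg.boundary_column + 1
                            if seg.boundary_column is not None else ""),
        "left_pct_id": round(100 * seg.left_mean, 1),
        "right_pct_id": round(100 * seg.right_mean, 1),
        "n_variant": variants.n_variant,
        "n_substitution": variants.n_substitution,
        "n_indel": variants.n_indel,
    }])
    _write_tsv(seg_df, os.path.join(config.out_dir, "segments.tsv"), config)
    if cargo_interval is not None:
        s, e = cargo_interval
        leader = selection.RegionMask("leader", ((s, s + config.leader_bp),))
        mature = selection.RegionMask("mature", ((s + config.leader_bp, e),))
        rows = []
        for i in range(msa.n_rows):
            for j in range(i + 1, msa.n_rows):
                for mask in (leader, mature):
                    try:
                        r = selection.ng86_pair(msa.rows[i], msa.rows[j], mask)
                    except selection.KaKsError as exc:
                        log.warning("pair (%s, %s) %s: %s", msa.names[i],
                                    msa.names[j], mask.name, exc)
                        continue
                    rows.append({
                        "seq1": msa.names[i], "seq2": msa.names[j],
                        "region": mask.name, "Sd": r.Sd, "Nd": r.Nd,
                        "Ka": r.Ka, "Ks": r.Ks,
                        "ratio": r.ratio if r.ratio is not None else r.status,
                    })
        kaks_df = pd.DataFrame(rows)
        out["kaks"] = kaks_df
        _write_tsv(kaks_df, os.path.join(config.out_dir, "kaks.tsv"), config)
    return out


# ---------------------------------------------------------------------------

def load_rate_models(path: str) -> list[phylodating.RateModel]:
    """rates.yaml: list of {name, kind, rate_per_year? , mu_per_gen?,
    doubling_days?, calibration_branch_length?, calibration_years?}."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    models = []
    for e in entries:
        kind = e["kind"]
        if kind == "per_year_direct":
            models.append(phylodating.RateModel(e["name"], kind,
                                                float(e["rate_per_year"])))
        elif kind == "calibrated":
            models.append(phylodating.calibrate_rate(
                float(e["calibration_branch_length"]),
                float(e["calibration_years"]),
                sig_figs=e.get("sig_figs"), name=e["name"]))
        elif kind == "per_generation":
            models.append(phylodating.rate_from_generation(
                float(e["mu_per_gen"]), float(e["doubling_days"]),
                name=e["name"]))
        else:
            raise ValueError(f"unknown rate model kind {kind!r}")
    return models


def run_dating(divergences: list[tuple[str, str, list[str]]],
               models: list[phylodating.RateModel], config: RunConfig,
               mode: str = "root_height") -> pd.DataFrame:
    """Ages (years) for named divergences, each given as (name, newick
    path/string, clade leaf list), one column per rate model."""
    named = []
    for name, source, clade in divergences:
        tree = read_tree(source)
        bl = phylodating.mrca_branch_length(tree, clade, mode)
        named.append((name, bl))
    table = phylodating.build_age_table(named, models)
    _write_tsv(table.reset_index(names="divergence"),
               os.path.join(config.out_dir, "ages.tsv"), config)
    return table
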