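"""Distance-based tree utilities and multi-rate molecular dating.

Divergence ages are branch lengths (expected substitutions per site)
divided by a per-year substitution rate.  Three kinds of rate model are
supported: a rate stated directly per year, a rate calibrated from an
observed branch length over a known number of years (e.g. a strain and its
resequenced sister culture separated by 16 years), and a per-generation
mutation rate converted through a doubling time (365.25-day years).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .seqio import PhyloTree, ValidationError, read_tree

DAYS_PER_YEAR = 365.25


@dataclass
class DistanceMatrix:
    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names), len(self.names)):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix not symmetric")
        if (v < 0).any():
            raise ValidationError("negative distances")
        self.values = v


@dataclass
class RateModel:
    name: str
    kind: str                       # per_year_direct | calibrated | per_generation
    rate_per_year: float
    mutation_rate_per_generation: float | None = None
    doubling_time_days: float | None = None
    calibration: tuple[float, float] | None = None   # (branch_length, years)

    def __post_init__(self):
        if self.rate_per_year <= 0:
            raise ValueError("rate_per_year must be positive")
        if self.kind == "per_generation" and (
                self.mutation_rate_per_generation is None
                or self.doubling_time_days is None):
            raise ValueError("per_generation model needs mu and doubling time")
        if self.kind == "calibrated" and self.calibration is None:
            raise ValueError("calibrated model needs a calibration pair")


@dataclass
class AgeEstimate:
    divergence_name: str
    rate_model: str
    branch_length: float
    age_years: float

    @property
    def age_Mya(self) -> float:
        return self.age_years / 1e6


# ---------------------------------------------------------------------------

def jc69_distance(p: float) -> float:
    """Jukes-Cantor distance from a raw mismatch fraction."""
    if not 0 <= p < 0.75:
        raise ValueError(f"mismatch fraction {p} outside [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def alignment_distance_matrix(msa) -> DistanceMatrix:
    """Pairwise JC69 distances between alignment rows (gap/N excluded)."""
    m = msa.matrix()
    ok = (m != ord("-")) & (m != ord("N"))
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            tot = int(both.sum())
            if tot == 0:
                raise ValueError("no comparable sites between rows")
            p = float(((m[i] != m[j]) & both).sum() / tot)
            d[i, j] = d[j, i] = jc69_distance(p)
    return DistanceMatrix(list(msa.names), d)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree; negative branch lengths clamped to zero."""
    if len(dm.names) < 3:
        raise ValueError("need >= 3 taxa")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    sk = skbio_nj(SkbioDM(dm.values, ids=dm.names))
    for node in sk.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    newick = str(sk)
    return read_tree(newick)


# ---------------------------------------------------------------------------

def round_sig(x: float, sig_figs: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig_figs - 1)


def calibrate_rate(mean_branch_length: float, divergence_years: float,
                   sig_figs: int | None = None,
                   name: str = "calibrated") -> RateModel:
    """Per-year substitution rate from an observed branch length over a
    known divergence time; optionally rounded to ``sig_figs`` significant
    figures for reporting."""
    if mean_branch_length <= 0 or divergence_years <= 0:
        raise ValueError("inputs must be positive")
    rate = mean_branch_length / divergence_years
    if sig_figs is not None:
        rate = round_sig(rate, sig_figs)
    return RateModel(name, "calibrated", rate,
                     calibration=(mean_branch_length, divergence_years))


def rate_from_generation(mu_per_gen: float, doubling_days: float,
                         name: str = "per_generation") -> RateModel:
    """Per-year rate from a per-generation mutation rate and a doubling
    time in days (one generation per doubling)."""
    if mu_per_gen <= 0 or doubling_days <= 0:
        raise ValueError("inputs must be positive")
    rate = mu_per_gen * (DAYS_PER_YEAR / doubling_days)
    return RateModel(name, "per_generation", rate,
                     mutation_rate_per_generation=mu_per_gen,
                     doubling_time_days=doubling_days)


def age_estimate(branch_length: float, model: RateModel,
                 divergence_name: str = "") -> AgeEstimate:
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    return AgeEstimate(divergence_name, model.name, branch_length,
                       branch_length / model.rate_per_year)


def mrca_branch_length(tree: PhyloTree, clade: list[str],
                       mode: str = "root_height") -> float:
    """Branch length from the MRCA of ``clade`` to its tips.

    ``root_height``: the maximum MRCA-to-tip path; ``mean_tip_path``: the
    mean.  For a two-leaf clade on a clock tree both equal half the
    patristic distance.
    """
    t = tree.tree
    t.is_rooted = True          # MRCA is defined w.r.t. the seed node
    labels = set(clade)
    taxa = [lf.taxon for lf in t.leaf_node_iter()
            if lf.taxon.label in labels]
    if len(taxa) != len(labels):
        missing = labels - {x.label for x in taxa}
        raise ValueError(f"clade leaves absent from tree: {sorted(missing)}")
    mrca = t.mrca(taxa=taxa)
    depths = []
    for lf in mrca.leaf_iter():
        if lf.taxon.label not in labels:
            continue
        d, node = 0.0, lf
        while node is not mrca:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    if mode == "root_height":
        return max(depths)
    if mode == "mean_tip_path":
        return float(np.mean(depths))
    raise ValueError(f"unknown mode {mode!r}")


def clock_root_height(tree: PhyloTree) -> float:
    """Root height of a clock-like tree whose rooting is unknown (e.g. a
    neighbor-joining tree): half the largest patristic distance, which is
    the root-to-tip path after midpoint rooting."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = list(tree.tree.taxon_namespace)
    best = 0.0
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            best = max(best, pdm.distance(a, b))
    return best / 2.0


def build_age_table(divergences: list[tuple[str, float]],
                    models: list[RateModel]) -> pd.DataFrame:
    """Age table: one row per named divergence (branch length in
    substitutions/site), one column per rate model, ages in years."""
    data = {}
    for model in models:
        data[model.name] = [age_estimate(bl, model, name).age_years
                            for name, bl in divergences]
    return pd.DataFrame(data, index=[name for name, _ in divergences])
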