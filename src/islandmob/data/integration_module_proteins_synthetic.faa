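>dsiB synthetic reference, 540 aa
MEKLAMLDEHIFPKPQNPNGEKIDSLPPWKGMFKCQINELHQKCHCYSPTVFAKFTADMDRLIGGTTCHA
DNRAWQHSDASWMSPVVKIFAGNASGNKPVWSHTEILEYGQCLKNGEEWYQVKRHEEQGGMKCIKFYPAE
NQYFAVQTTIKQGVNEWEWKGCCYGMLPYYTMLSHMSCYVWCKLVFNCVDDIFQLARIAKGSWTYYPYQS
KDNRPCWMSNWCYQPCMFWWSPKNSSGVHPLAFRDAVMSTLINHNALNAVPGMFRTAWRIAALEMMVCMD
MGVGSKDYCYLCWTYLNWRAFIQDEYIKYQQGMPAGKQPWYFQCDFCTQTFMDISFMMHINVWYKQEVFE
NITISCYRSNAKGEGIHRPNISPWSIHLCHYLYYKKGCSPWIMTSSWQFWKQNESDNTRCVECFAWQGSV
LGKLPHYMDDEVYDNDACRKHHDPTWYWNKTTEMTQRQCERWKLKCAVGFISTESHVIGDRVAFIMTGAY
YFKHIWMFQCLQPMRFCDIFPCKHAIPQAAHKVFDYCIMNSVYDLDEIWF
>dsiA synthetic reference, 200 aa
MKEFIVRHKKSDSNYFHLMEPCRGWMHEMHHEHNGPYLNFFQLKRCHSQWQMMCEGGIGFRQISNWIVTS
KMSDKMTCQLHEGLHRARTHMTTMYTCPGSSTTKNDWGFFCKGCEGTATNQPQVMFCYKNWRKHSGHCMN
LLDMPFNCFRKWPNPWFYSEDLNEGEMMVLNDWRLIYHWDIRTAFFWMSVFFQREDPFIP
>recF-like synthetic reference, 150 aa
MEHHKMDPWTVWYPTNSEVLWPYWLTDVTCVYKHYIKNCLGSGFFWHRCRQLWREHWEHKQKQPMYWCLS
YACVMWKGIKMNVSLYQACRSTAEKGYQMNGKHRITEQFDNIEDIYCLQIMWGEPCPFMNTEVYHISKFG
CEWICAMVEH
>parB-like synthetic reference, 210 aa
MQERWHCSYFLLCYLAGSNIWIAYWVDEAVWAPFGILKFRWPNEGEAGVTVIDADGSVTDGDHYATIKFL
ECDKFLPKFCNKLQKHMGVDTWSVRTWSKGPKCEQEYQDLQWNGRYRCPCLGKNAHCMHPAANEIQYHFI
RFHAPPTHWMNQKAVHPDHGIWKLEQLRMYTTDCSEIYMQKAHDPMAHDYCIRCLASFGMPPRCETLQAF
>mom-like synthetic reference, 270 aa
MRRCELTMWDDMPCGVSFKHLAMMTCEALHLFDKMCGQHHKDGCKKTIIIIELKPQLAIDPNVWGYVKTP
DACTVQRKPQGADGSYDGNKQWEFCTTIWHQWECSYGMISNKIVLHSKMWYCWYQRDEHYDQYKRWTYRD
SGCFKEYNCTGCGCGHFTHTMVMPPYYQDASCEGAWPPPATLWNCPHCQIRYVRWAKPPFMDVSYVQPLL
NNYEFREGKPWGGWEHLPQYFIQRVYKQATRWVCSVEGFIWVGRIEGAFRNLCYQCYLHR
>rnap-domain synthetic reference, 700 aa
MEDNLTWCVVAFGYDWCVSWMWTMQGIWKHFIAPMMHSRWIQYLCNCPICRQDFRLMNDSIEQYVLCCEN
WVCFCTTGYTAHCAWLQDTHSELCFCKTLLRPGHWVCCINTTRHSCCHMWNWCMHYDETKGEMMSQVWNH
GAQKLLGQILFRWLPDMVPMSMQGEWMKVPNNGTNLFSDNNHANWRTNCECFCFQGTWVEQQQICMCGSV
CPERFRIVVFQCATHYHLAECCYIMHIHGLHVTYTNQTFRYTYQSRDKRKGDYAWSPLGCVMNFCLALHG
QSQGHCIQSFFNKPEDEFISLKGAGYWLPQNNHGQLMDYWKYGYECEFGMDNVGKANVPDQESPDVMSWC
PELQLDMHECMPVDEGLMFECFYAVGSENIVANECSGDCYFCYEMQQCMHQHCMWNDNCGIPVPLAMRTD
YLWQKLWLWRKQHAISWDAVAKCYNGYNDLLFSGSRREHMCQVCHLRRPLEMWFCNAETTTYYLAMSMYL
AEMYSMEVTQSIKSKNWMFWHPRYMGYFIWYAREELGGIQYPYSWRAIAIMIEPVLYKILQSCKWMDMYF
CRSAPPRWPALLKQQLMIDGPRHKQMYQTPMTDLPKEKWEWYNNHNEASRATLIAFTMGYVLTHSVAAGS
SARGIFNFGRRLLLTWLLVWAFMVFHQDMHDRFIPKQRDYYTEGIWHDDNGSYIIELIKNPDKYHYNKDN
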