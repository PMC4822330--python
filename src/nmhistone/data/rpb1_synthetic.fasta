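>Rpb1 SYNTHETIC Rpb1-like reference: generated body (seed 20260924) + 52 YSPTSPS heptads; not a natural sequence
GRRDLMFLYAQMQLAPQCKEKHFTYDSYEHMTIYLQADRNKQRRKGANSCFLWNMNKWAK
VGHLCNQPPPFWTDYVFMHLKWQYDVEKDSQCLVDNSNVQLGLREITYLQDKCTWNDPDE
NRQRKCFHVFCHEHILDCHMMYPVQHKQAAEKMFLVVPDSLMAPLAHRNNNGESSTFGGW
GWSGRHSYKQIFAPIERICAWSVNEYPQFQEMQDHQIARRMCKRPGTIEAMDPFYNEHKD
PCFWCLYDKLHCQGCDMNLDRITQLMSNQHAADWSLRYDMSLPSAKYTCIDVRMHVLRHL
CQTEGPSCAMNGSANGKCEKHIQTWSHEKAKMRSFYKYTQQVFAYGEKYGVLIYPGRRDS
VTCLMWAYDWVQCALIHHLPVHILHCFKYISSNENFIFNNSDEDAHEWDREQFMALSYSR
QDSIWDPRKHDYCSYGNMCFRPKNWKHQLSFMRLPLIYNFSPNHSGWTGQTKNHAYTMDA
SYKQTHLPAFGKFYNGSWWMLTIIHTYSTALKGSTPYECWPCAHYAKQVNAPPMSYVFTR
AVVCTAFCIEDSQPAYLDQMTNAAELAEMHCDFVSYDSAQDWFTKAWQEVSQMPWGCFKI
WVIDITFIPCCKVNRNEPSACWFLDAPGSFRASWGSEYHEDSMEDSYTRATIPSWDQPEM
FYRSIHFQQHPQAPYVMTVPLCGYLHEDQHTYDYNVCDLSRTIHFEAQYFLDMSHMRECE
HLRPQIMEFKHQIGSLCMSQNWGMRMNWFCVYPCYALRVLDLQMRWCPITFWIGYWMYGT
AAKEDGWARFDLNEMSDWGTWGSDARFPTKTFSEAGTTFYPSNSMFNIAMDDVIMPARDK
MGPNVQDVRYWEDNPHSRFPHCAANFDPFMKLEGKGCYQAPKHNPHRSAQPQGMTGFAMA
EWYIQNCVKFWNDMWVFLMQPYNLDWDAEPDQLRMKEPMMMAKRPHKKKGYRTAQTRKHG
YRAMTHTWTRLRDGADINIPAFIKPIRHMRLIAWLYKGPIMIPTSLTMADFSRGYVICKW
WTYIRVPGEWCTQSKRKSWNFDQQRQIYNGQFVVGEQIGQCIEGLDVVETTNWTFPHMDC
RMEIIIGVTNQITNDYHPYQALSYKCDKDQLVVNPVDVPQVPCHARVSVSTRLVHWVRIK
DWQGQRILYVLKRVLIRLLMYTIPMTVPGQGGKNWVWIAVSDDCVNVSVKPLIKGNAPPQ
RSMMEYAEWGFLQYRDTVYFWISHYLGLGPETKYWPTDSLPGIGNNHFWDLWEQTDSTHY
HHREWARHHIHLARWKFRHFDNDCYVAAMILWRYTQTMQTRHGVCRRGGRSMDDWADRYK
SLVAEVMNTGNPDNWAPLFIAKCRQHHVVHWMVTRMACRKRHGGRDQPFQEVHSSIFEWH
DITYHMNKQNFNFCSTMKKCIEGCPKLPLQWLASFHCHMCCDYRYTERPSEMLNWACDYH
CVFWYDFVMMAKYLVYNCRPYVSPHVQPSHMRITANPWWKESHIIYTMCDGRNGLESCDQ
YSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPT
SPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSY
SPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTS
PSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYS
PTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSP
SYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSPTSPSYSP
TSPSARYNISPTADTL
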