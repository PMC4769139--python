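>lrr_plant_consensus family=LRR synthetic plant-type LRR exemplar built from the LxxLxxLxLxxNxLTGxIP repeat period of extracellular LRR proteins
PNLTELDLGNNKLTGKIPEELGNLKNLQVLDLGNNKLTGEIPKELGNLKELTLLNLANNN
LTGKIPEELGKLTNLVELDLGNNKLTGKIPAELGNLKNLQKLDLANNELTGPIPKELGKL
ENLTLLNLGNNKLTGKIPEELANLKNLVELNLANNKLTGKIPDELGNLKNLE
>kinase_stk_consensus family=KINASE synthetic Ser/Thr protein-kinase catalytic exemplar carrying the canonical VAVK, HRDLKP.N, DFG and APE subdomain anchors
MGFGKELGRGAFGKVFKGTLPNGTEVAVKRLKDVNQGGEAEFLAEVEMLGRLHHRNLVKL
LGFCNEGNERLLVFELMPNGTLEDHLHGPNKPTLDWPTRLKIALGAARGLAFLHEGAEPP
VIHRDLKPGNILLDHNFEPKVADFGLAKLLPDGETHVTTRVMGTFGHVAPEWLKTGKPTT
KSDVFGFGVVLLELLTGRKPVDMGQPQGEENLVTWARPLLANREGLEQLVDPRLGGDFNP
EEMKRVILVALLCTQGNPEDRPTMGEVVKMLEGEMEVR
>fh2_formin_consensus family=FH2 synthetic formin-homology-2 exemplar modeled on the lasso/post architecture of FH2 dimerization domains
PEFLKNPEKFTELAPLFHTQTPKPDLKELKKPEAPKTTEPKVQLIDPKKAQNLAITLRAL
NVTAEEVCDALLEGNELPVELLQTLLKMAPTEEEELKLKEHKDDPNKLGPAEHFLLELAE
VPRFAERLNVWAFKMDFETTEKEIAEPLAVLKKATEELRNGKTLRKLLEIVLAMGNFLNG
GTARGNAVGFRLDTLLKLADTRANNNKMTLMHFLVQVLEEKFPDVLHFPEELEHVEKAAK
VQLENLQKDLKQLEKDLEACEAELKAQDGPFAEVMKPFLETAEKELEELEDQLKNMEAL
>globular_helix_bundle family=OTHER synthetic generic globular helix-bundle exemplar used as a foreign-domain control
MKVEELAKDLGLTNEQVLEAIKAGNVKELQDLGVRTLDLVKHFGGELAEKLGVKLGDVIE
AFEKGAIDEKTLKELKDHPEVFEKFGLEKLAELLEGGVTPEMLEKVHKELGLDEETVKKV
LDEVK
>classical_ext_repeat family=CLASSICAL_EXT synthetic classical-extensin repeat-region exemplar (Ser-Pro4 units interleaved with Tyr cross-link triplets)
SPPPPYVYKSPPPPYVYKSPPPPSPSPPPPYVYKSPPPPYHYKSPPPPKHSPPPPVYKYK
SPPPPSPSPPPPYVYKSPPPP
>short_ext_repeat family=SHORT_EXT synthetic short-extensin repeat exemplar (sparser Ser-Pro4 units with single Tyr triplets)
SPPPPVKHYTYKSPPPPKVPVYKSPPPPVHHYKYKSPPPPHKV
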