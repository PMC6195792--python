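# Mini cis-element table in PLACE Signal-Scan format (element_id, IUPAC).
# Sequences entered by hand from the public PLACE motif records
# (https://www.dna.affrc.go.jp/PLACE/); this is a small curated subset,
# not a redistribution of the database.
element_id	iupac
CACTFTPPCA1	YACT
EBOXBNNAPA	CANNTG
DOFCOREZM	AAAG
MYCCONSENSUSAT	CANNTG
CAATBOX1	CAAT
GTGANTG10	GTGA
WRKY71OS	TGAC
GT1CONSENSUS	GRWAAW
ROOTMOTIFTAPOX1	ATATT
POLLEN1LELAT52	AGAAA
MYBCORE	CNGTTR
OSE2ROOTNODULE	CTCTT
ACGTCBOX	GACGTC
TATABOX3	TATTAAT
CTRMCAMV35S	TCTCTCTCT
HDZIP2ATATHB2	TAATMATTA
CANBNNAPA	CNAACAC
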