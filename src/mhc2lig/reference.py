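"""Published per-allele HLA-DR ligand count distributions.

Counts of unique SYFPEITHI-derived MHC class II ligands per HLA-DR allele
for the two benchmark datasets used by this package's evaluation setup.
They serve as fixed reference inputs for dataset accounting: the training
distribution totals 644 ligands over 22 alleles (290 after capping each
allele at 30), the test distribution 697 ligands over 28 alleles.
"""

TRAINING_ALLELE_COUNTS: dict[str, int] = {
    "DRB1*0101": 13,
    "DRB1*0102": 5,
    "DRB1*0301": 20,
    "DRB1*0401": 365,
    "DRB1*0402": 33,
    "DRB1*0404": 43,
    "DRB1*0405": 26,
    "DRB1*0701": 23,
    "DRB1*0801": 33,
    "DRB1*0901": 4,
    "DRB1*1001": 1,
    "DRB1*1101": 16,
    "DRB1*1104": 7,
    "DRB1*1201": 8,
    "DRB1*1301": 14,
    "DRB1*1302": 14,
    "DRB1*1401": 3,
    "DRB1*1501": 2,
    "DRB3*0202": 3,
    "DRB3*0301": 3,
    "DRB4*0101": 1,
    "DRB5*0101": 7,
}

TEST_ALLELE_COUNTS: dict[str, int] = {
    "DRB1*0101": 47,
    "DRB1*0102": 1,
    "DRB1*0301": 89,
    "DRB1*0401": 154,
    "DRB1*0402": 4,
    "DRB1*0403": 1,
    "DRB1*0404": 4,
    "DRB1*0405": 10,
    "DRB1*0701": 27,
    "DRB1*0801": 7,
    "DRB1*0802": 1,
    "DRB1*0803": 1,
    "DRB1*0901": 2,
    "DRB1*1001": 241,
    "DRB1*1101": 20,
    "DRB1*1104": 2,
    "DRB1*1201": 6,
    "DRB1*1301": 12,
    "DRB1*1302": 9,
    "DRB1*1401": 7,
    "DRB1*1501": 21,
    "DRB1*1502": 3,
    "DRB1*1601": 2,
    "DRB3*0101": 3,
    "DRB3*0301": 2,
    "DRB4*0101": 5,
    "DRB4*0103": 2,
    "DRB5*0101": 14,
}

#: glycosylation counts over the 459 affinity-matched ligand/non-ligand pairs
#: of the published comparison (ligand count, non-ligand count)
MATCHED_GLYC_COUNTS: dict[str, tuple[int, int]] = {
    "any": (27, 50),
    "nglyc": (20, 40),
    "oglyc": (7, 10),
}
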