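"""Named exemplar structures with literature-standard SMILES.

The Ro5 group are prevalent small natural products (sugars, amino acids);
the bRo5 group are large natural-product drugs.  Heparin is excluded: it is
a polydisperse polymer without a single representative structure.
"""

RO5_EXEMPLARS = {
    "sorbose": "OCC(=O)[C@@H](O)[C@H](O)[C@H](O)CO",
    "mannose": "OC[C@H]1OC(O)[C@@H](O)[C@@H](O)[C@@H]1O",
    "histidine": "N[C@@H](Cc1c[nH]cn1)C(=O)O",
    "arginine": "N[C@@H](CCCNC(=N)N)C(=O)O",
}

BRO5_EXEMPLARS = {
    "paclitaxel": (
        "CC1=C2[C@@H](C(=O)[C@@]3([C@H](C[C@@H]4[C@]([C@H]3[C@@H]([C@@](C2(C)C)"
        "(C[C@@H]1OC(=O)[C@@H]([C@H](c1ccccc1)NC(=O)c1ccccc1)O)O)OC(=O)c1ccccc1)"
        "(CO4)OC(C)=O)O)C)OC(C)=O"
    ),
    "doxorubicin": (
        "COc1cccc2c1C(=O)c1c(O)c3c(c(O)c1C2=O)C[C@@](O)(C(=O)CO)C[C@@H]3O"
        "[C@H]1C[C@H](N)[C@H](O)[C@H](C)O1"
    ),
    "streptomycin": (
        "CC1C(C(C(O1)OC2C(C(C(C(C2O)O)N=C(N)N)O)N=C(N)N)OC3C(C(C(C(O3)CO)O)O)NC)"
        "(C=O)O"
    ),
    "bleomycin": (
        "CC1=C(N=C(N=C1N)C(CC(=O)N)NCC(C(=O)N)N)C(=O)NC(C(C2=CN=CN2)OC3C(C(C(C(O3)"
        "CO)O)O)OC4C(C(C(C(O4)CO)O)OC(=O)N)O)C(=O)NC(C)C(C(C)C(=O)NC(C(C)O)C(=O)"
        "NCCC5=NC(=CS5)C6=NC(=CS6)C(=O)NCCC[S+](C)C)O"
    ),
}
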