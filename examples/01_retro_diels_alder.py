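"""Locate Diels-Alder reactive sites and apply the retro transformation.

Each cycloadduct is searched for cyclohexene substructures; every site
found is a competing retro pathway.  The printed products are the diene
and dienophile that would re-form the adduct in the forward reaction
(verified by the round-trip check).
"""

from daforge import Cycloadduct, find_reactive_sites, forward_check, retro_transform

ADDUCTS = {
    "cyclohexene": "C1=CCCCC1",
    "4-vinylcyclohexene": "C=CC1CCC=CC1",
    "bicyclic (intramolecular)": "C1=CCCC2CCCCC12",
    "two competing sites": "C1=CC(CCC1)C1CCC=CC1",
}

for name, smiles in ADDUCTS.items():
    adduct = Cycloadduct.from_smiles(smiles)
    sites = find_reactive_sites(adduct)
    print(f"{name}: {smiles}  ->  {len(sites)} reactive site(s)")
    for k, site in enumerate(sites):
        products = retro_transform(adduct, site)
        tag = "intramolecular" if products.intramolecular else "two fragments"
        ok = forward_check(products, adduct)
        print(f"  site {k}: diene atoms {site.diene_atoms}, "
              f"dienophile atoms {site.dienophile_atoms}")
        print(f"          retro products: {products.combined_smiles} "
              f"({tag}, round-trip {'ok' if ok else 'FAILED'})")
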