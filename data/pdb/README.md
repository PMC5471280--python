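# Deposited coordinate files (not redistributed)

The structural acceptance tests read the deposited crystal structures of
the ERβ/ERα ligand-binding domains from this directory as lowercase
`<id>.pdb` files:

- `5toa.pdb` — alternative ERβ LBD–estradiol conformer
- `3ols.pdb` — canonical agonist ERβ LBD–estradiol
- `3oll.pdb` — phosphorylated canonical ERβ LBD–estradiol
- `1qkm.pdb` — antagonist-like ERβ LBD–genistein

Download them from the PDB, e.g.:

    for id in 5TOA 3OLS 3OLL 1QKM; do
        curl -o data/pdb/$(echo $id | tr A-Z a-z).pdb \
            https://files.rcsb.org/download/$id.pdb
    done

Without these files the five deposited-structure acceptance tests fail
with a message naming what is missing; everything else in the test suite
is self-contained.
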