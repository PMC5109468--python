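# Accession files (optional)

Place deposited PDB-format coordinate files here to enable the accession
spot-checks (`scripts/acceptance.py` targets t1–t6 and the optional tests in
`tests/test_acceptance.py`):

    4mv2.pdb  4b1y.pdb  4m83.pdb  3wl2.pdb

e.g. `curl -O https://files.rcsb.org/download/4MV2.pdb` (rename to
lowercase). The repository ships without them; everything else is tested
with synthetic fixtures.
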