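# External inputs (not distributed)

Two integration checks consume files that must be downloaded separately and
placed in this directory:

- `yeast_v7.xml` — the Yeast 7.0.0 consensus genome-scale model (SBML),
  as distributed by the yeast metabolic network consortium. Used to
  reproduce the wild-type growth rate of 0.1405 hr^-1 under the model's
  default aerobic glucose minimal medium and the zero wild-type flux
  through the glutathione synthase reaction `r_0485`.
- `candidate_pairs.faa` — UniProt sequences (one FASTA, accession as the
  first header token) for the 11 candidate human proteins and their yeast
  ortholog partners listed in the packaged tables. Used for the end-to-end
  active-site conservation check (10 of 11 pairs conserved; the
  delta-aminolevulinic acid dehydratase site maps human 221 -> yeast 232).

Without these files the two corresponding integration tests in
`tests/test_acceptance.py` fail with a pointer to this README; every other
test runs from packaged or generated data.
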