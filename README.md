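# orthoflux

Tools for asking a concrete comparative-genomics question: **when a human
enzyme carries a nonsynonymous variant at its catalytic (active-site)
residue, can a yeast knockout model predict the metabolic consequence?**

The package chains the four analysis stages needed to answer it:

1. **Orthology** (`orthoflux.orthology`) — reciprocal best-hit (RBH)
   detection between a human and a yeast proteome. Every query is
   classified `NO_HIT`, `PARALOGOUS` (its best subject belongs to a
   higher-scoring query), `ONE_WAY_BEST`, or `RECIPROCAL`. Hits come from a
   12-column tabular search report or from the built-in optimal aligner
   (BLOSUM62, affine gaps, global or local).
2. **Conservation** (`orthoflux.conservation`) — maps annotated active-site
   positions through the gapped pairwise alignment (1-based sequence
   coordinates, 0-based alignment columns), judges conservation (identical
   residue at the mapped position, consistent with the partner's own
   curated annotation when present), and extracts the conserved block
   around the site (identities as letters, positive mismatches as `+`).
3. **Annotation filter** (`orthoflux.annotation`) — the five-stage
   candidate cascade: 1 enzyme : 1 pathway : 1 reaction, reciprocal
   ortholog, active-site conservation, no close paralogs, and
   pathway/substrate/product conservation (exact PubChem CID/SID set
   equality).
4. **FBA core** (`orthoflux.fba`) — from-scratch constraint-based
   modelling: maximize biomass flux v_bm subject to S·v = 0 and
   lb ≤ v ≤ ub; minimize the taxicab norm Σ|v| at the attained optimum
   (split-variable LP, suppresses futile cycles); evaluate boolean
   gene-protein-reaction rules to propagate gene knockouts to reaction
   bounds; augment the biomass function with small extra metabolite
   requirements (default 0.0005 per unit growth) in coefficient or demand
   mode. Models load from SBML L3+FBC or a native JSON dialect.

Deterministic synthetic generators (`orthoflux.synthetic`) provide
planted-ortholog proteomes and hand-solvable toy metabolic models, and
`orthoflux.fixtures` ships curated reference tables for the published
six-candidate human/yeast enzyme study (113 ortholog pairs, 34 active-site
variant candidates, site positions, pathway comparisons).

## Worked example

```bash
# a toy model with a cofactor branch behind a two-gene AND complex
printf 'include_cofactor_branch: true\n' > toy.yaml
orthoflux simulate model --config toy.yaml --out toy.json
# wrote toy.json; closed-form WT growth 14.0

orthoflux fba --model toy.json --knockout g_cof1 \
    --augment COF=0.0005 --mode coefficient --out panel.tsv
cat panel.tsv
```

```
target	kind	biomass_variant	growth_rate	classification	wt_ratio	disabled_reactions
WT	wild-type	original	14.000000	GROWTH	1.0000
g_cof1	gene	original	14.000000	GROWTH	1.0000	cof_synth
WT	wild-type	augmented	14.000000	GROWTH	1.0000
g_cof1	gene	augmented	0.000000	NO_GROWTH	0.0000	cof_synth
```

Reading the panel: the toy's two carbon branches supply 10 + 4 flux units
of precursor at yield 1, so wild-type growth is 14 (closed form). Deleting
`g_cof1` disables the cofactor synthase (an AND complex), which the
original biomass never consumes — growth is untouched. Once the biomass is
augmented with a 0.0005 cofactor requirement per unit growth, the same
knockout abolishes growth entirely. This is exactly the augmented-biomass
logic used to expose cofactor-pathway enzymes (heme synthesis,
mitochondrial tRNA charging) that a stock biomass function cannot see.

The full pipeline runs from one YAML config:

```bash
orthoflux run --config pipeline.yaml   # stages: rbh -> conserve -> filter -> fba
```

Each stage writes a TSV with a commented header carrying the config hash,
and `manifest.json` records input/output checksums; identical configs and
inputs reproduce identical bytes.

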