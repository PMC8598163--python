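# coilsig

Evolutionary-signature analysis of coiled-coil proteins: conservation
scoring, indel-depletion testing, and orthogroup screening.

## The problem

Synaptonemal-complex (SC) central-region proteins — and a growing list
of other structural proteins — evolve near-neutrally at the sequence
level yet conserve their *architecture*: overall length and the position
and extent of their coiled-coil domains.  Conventional per-site
conservation analysis is blind to this.  `coilsig` quantifies the
signature directly and uses it to find candidate structural proteins
that homology search cannot.

For an orthogroup alignment with members from species `s = 1..n`,
`coilsig` computes three metrics:

* **Substitutions per site**: the mean over all pairs of the
  gamma-corrected Poisson distance
  `d = a[(1 − p)^(−1/a) − 1]`,
  with `p` the pairwise difference proportion (pairwise deletion) and
  `a = 2` the gamma shape of among-site rate variation.
* **Coefficient of variation of protein length**:
  `CV = sd(L_1..L_n) / mean(L_1..L_n)` over ungapped member lengths.
* **Coiled-coil conservation score**: with per-residue coiled-coil
  scores `c_s(i) ∈ [0, 1]` (1 − Paircoil2-style p-score) threaded onto
  alignment columns and low-coverage columns (< 80% of species) removed,
  `score = mean_over_columns( min_over_species c_s(col) )`.
  It is high only where every species places a coiled-coil at the same
  aligned position.

The signature of an SC-like protein is *high* divergence, *low* length
CV, and *high* coiled-coil conservation.  Supporting machinery includes
a heptad-repeat per-residue scorer (any external predictor's profiles
can be substituted), conserved-domain calling (runs of ≥ 21 columns with
mean score > 0.8 and SD < 0.1), a phylogeny-aware indel census (Fitch
parsimony on gap patterns, two-sided Fisher exact test for depletion of
indels inside coiled-coils), a proteome screen with ranking and
complete-linkage clustering, a Polo-box (S-[S/T]-P) motif scan, and a
ground-truth simulator of protein-family evolution (true alignments,
event logs, planted coiled-coil segments) that makes every stage
testable offline.  See `docs/methods.md` for the full model description.

## Worked example

Simulate an SC-like family (12 species, true mean pairwise divergence
1.5 substitutions/site, two coiled-coil segments with five-fold indel
suppression), then run the signature and the indel census on it:

```python
import coilsig as cs
from coilsig import CoilDomain

fam = cs.simulate_family(cs.sc_like_config(seed=7, orthogroup_id="OG0001"))
m = cs.signature_metrics(fam.alignment, fam.profiles)
print(f"substitutions/site = {m.substitutions_per_site:.2f}")
print(f"CV of length       = {m.cv_length:.3f}")
print(f"cc conservation    = {m.cc_conservation_score:.2f}")

events = cs.infer_indel_events(fam.alignment, fam.tree)
ref = next(iter(fam.alignment.rows))
domains = [CoilDomain(s, e, 1.0) for s, e in fam.tip_segments[ref]]
labels = cs.classify_columns(fam.alignment, events, domains, ref)
table = cs.build_contingency(labels)
p = cs.fisher_exact_two_sided(table)
print(f"indels: {table.indel_in}/{table.total_in} inside vs "
      f"{table.indel_out}/{table.total_out} outside, Fisher p = {p:.2g}")
```

Output:

```
substitutions/site = 1.20
CV of length       = 0.016
cc conservation    = 0.62
indels: 9/317 inside vs 33/158 outside, Fisher p = 3.5e-10
```

Reading it: the family is highly diverged (1.2 substitutions per site —
pairs share only ~45% identity), yet member lengths vary by under 2%
and the per-column minimum coiled-coil score averages 0.62, i.e. the
coiled-coils sit at the same aligned positions in all 12 species.  The
census finds indel-containing positions at 2.8% of coiled-coil columns
versus 21% outside — the depletion the signature predicts — with a
decisive two-sided Fisher p-value.

The same operations are available from the shell:

```bash
coilsig simulate --seed 7 --out fam/
coilsig signature --msa fam/alignment.fasta --profiles fam/profiles --out metrics.tsv
coilsig indels --msa fam/alignment.fasta --tree fam/tree.nwk \
    --reference t01 --domains domains.tsv --out census.tsv
coilsig screen --metrics metrics.tsv --thresholds thresholds.yaml --out candidates.tsv
coilsig cluster --metrics metrics.tsv -k 15 --out leaves.tsv
```

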