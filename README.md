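# tisdiv

Silent-site nucleotide diversity is depressed near the translation
initiation site (TIS) of bacterial genes: the first ~100–300 bases of a
coding sequence carry systematically less synonymous polymorphism than the
rest of the gene, which in turn drives the well-known positive correlation
between gene length and per-gene diversity. `tisdiv` quantifies this
gradient and relates it to its biological correlates across species. It is
a library for population-genomic analyses of bacterial strain panels, with
a thin CLI for running the stages from a shell.

## The model

For an alignment column with base counts *f<sub>i</sub>* over *N*
sequences, per-site nucleotide diversity is

π = 2 Σ<sub>i&lt;j</sub> f<sub>i</sub> f<sub>j</sub> / (N(N−1)),

the probability that two strains drawn without replacement differ at the
site. Diversity is computed at 4-fold degenerate (silent) third codon
positions, classified from a ≥60% consensus sequence after excluding
columns with more than 70% gaps. Mean diversity π̄(l) at distance *l* from
the start codon, weighted by the number of contributing genes *w(l)*, is
fitted with the asymptotic (negative-exponential) regression

π̄(l) = d<sub>max</sub> + (d<sub>min</sub> − d<sub>max</sub>) e<sup>−cl</sup> + ε,  ε ∼ (0, σ²/w(l)),

giving two summary quantities with delta-method standard errors:

- **Effect Size** S<sub>e</sub> = log₂(d<sub>max</sub>/d<sub>min</sub>) — the log-2 fold reduction in
  diversity at the TIS relative to the asymptote;
- **Effect Length** L<sub>e</sub> = ln 2 / c — the distance at which diversity is
  halfway to saturation (the saturation point is conservatively 4 L<sub>e</sub>).

Around the structural side of the phenomenon, per-gene base-unpairing
probabilities over −100..+200 of the TIS are converted to flank-normalized
z-scores, yielding a structure effect length L<sub>ss</sub> (first position ≥ +5
where z drops to 0) and size S<sub>ss</sub> (maximum z). A comparative layer
relates effect lengths across species to recombination rate, rRNA count,
codon usage bias and strain count by phylogenetic generalized least
squares with Pagel's λ and by backward elimination under repeated 10-fold
cross-validation.

Every input the pipeline consumes can be generated synthetically with
known ground truth (`tisdiv.synthetic`), so all estimators are validated
by parameter recovery.

## Worked example

`examples/02_effect_length_fit.py` simulates a species at a realistic
scale (96 strains, 3000 genes, true L<sub>e</sub> = 76, S<sub>e</sub> = 2.2), fits the
asymptotic regression and prints:

```
truth:     Le =   76.0   Se =  2.20
estimate:  Le =   74.9 +- 2.9   Se =  2.22 +- 0.09
saturation point 4*Le = 300 bases
fold decrease at TIS  = 4.65x
```

The fitted effect length of 74.9 ± 2.9 bases recovers the generating value
within one standard error; an effect size of 2.22 means silent diversity
at the start codon is about 4.7-fold below its far-from-TIS level, and the
reduction has essentially saturated by ~300 bases into the gene. The other
scripts under `examples/` walk through site classification, strain
de-duplication, the TIS-structure z-profile, and the comparative layer.

The same stages are exposed as subcommands:

```bash
tisdiv simulate --out bundle --n-strains 96 --n-genes 800 --le 76
tisdiv species --alignments-dir bundle/alignments --unpaired bundle/unpaired.tsv --out-dir run
tisdiv comparative --species-table traits.tsv --tree species.nwk --out-dir run
```

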