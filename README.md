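# glycopssm

Composition-based prediction of O-GlcNAc glycosylation sites.

O-GlcNAc transferase (OGT) is the single enzyme that attaches
N-acetylglucosamine to serine/threonine residues of nuclear and
cytoplasmic proteins. Predicting which S/T sites it modifies is hard:
there is no crisp sequence motif, and most substrates are intrinsically
disordered regions (IDRs) that OGT's TPR superhelix appears to recognize
by amino-acid *composition* over a long stretch rather than by a short
linear motif. `glycopssm` is a toolkit for building and using that kind
of predictor. It is aimed at glycobiology and IDR labs who have (or want
to simulate) positive and verified-negative peptide sets and want a
transparent, trainable scoring model rather than a black box.

## The model

A candidate site is an S/T residue with its surrounding window of
`L = 39` residues (19 per side, `-`-padded at termini). A scoring matrix
`M(a, i)` assigns a value to each amino acid `a` at each non-center
offset `i ∈ {−19..−1, +1..+19}`, over 18 residues (the canonical 20 minus
the rare W and C) — an 18 × 38 table. A window scores

    S(w) = Σ_i M(w_i, i)

with W, C, X and pads contributing 0; a site is called positive when
`S(w) ≥ threshold` (defaults 123/148/160 for low/medium/high stringency).

The matrix is trained by randomized hill climbing against the matrix
assessment score

    MAS = (P − Pstd − N − Nstd) / P

where `P`/`N` are the medians and `Pstd`/`Nstd` the sample standard
deviations of the positive- and negative-set score distributions: each
iteration perturbs one random cell by ±1 and keeps the change iff MAS
strictly increases. The package also ships dataset diagnostics
(per-offset residue frequencies, exact-binomial compositional bias
against a background proteome composition, confusion-matrix evaluation
over a test protein's S/T sites) and a synthetic generator that plants a
known compositional contrast — substrate-like windows enriched in
A/V/T/I/L/M/P, non-substrate-like windows enriched in G/Q/N/D/E/R — so
the whole pipeline is testable without any external data.

See `docs/methods.md` for assumptions, numerical choices and known
limitations (including the behavior of the MAS ratio near `P = 0`).

## Worked example

Simulate the two populations, train a matrix, and read the learned
preferences off it:

```sh
glycopssm simulate --preset positive --n 500 --length 39 --seed 11 --out pos.tsv
glycopssm simulate --preset negative --n 500 --length 39 --seed 12 --out neg.tsv
glycopssm train pos.tsv neg.tsv --seed 13 --iterations 50000 --out-matrix matrix.tsv
# INFO glycopssm: final MAS 1250.513728 after 50000 iterations (872 accepted)
```

```python
>>> from glycopssm import read_matrix
>>> means = read_matrix("matrix.tsv").row_means()
>>> {aa: round(means[aa], 2) for aa in "AVTILMP"}
{'A': 0.36, 'V': 0.36, 'T': 0.19, 'I': 0.31, 'L': 0.47, 'M': 0.3, 'P': 0.47}
>>> {aa: round(means[aa], 2) for aa in "GQNDER"}
{'G': -1.05, 'Q': -0.75, 'N': -0.91, 'D': -0.87, 'E': -0.97, 'R': -1.2}
```

Every residue planted as favorable comes out with a positive mean matrix
row and every unfavorable one negative — the trainer has recovered the
planted compositional contrast from the data alone. `glycopssm predict`
then scores the S/T sites of any FASTA protein with a trained matrix,
and `glycopssm evaluate` compares calls against a known-site list:

```text
Positive sites found    1
Total sites found       2
Predicted sites verified        50%
Sensitivity     100%
Specificity     67%
Accuracy        75%
```

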