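# synovniche

Spatial and single-cell composition statistics for inflamed synovial tissue:
niche detection from local cell-type neighbourhoods, nearest-neighbour
co-localization with a permutation null, permutation differential cell-type
abundance, normality-gated correlation of niche proportions with Krenn
synovitis scores, marker-intensity cell annotation, gene-to-cell-state
mapping, and a simplified ligand–receptor interactome — plus a synthetic
synovium generator with planted ground truth so every statistic is testable
without patient data.

The package is aimed at analysts working with multiplexed spatial data
(Xenium-style transcript panels, CODEX/Cell DIVE-style multiplexed IF) from
synovial biopsies or similar layered tissues, where per-cell coordinates,
cell-type labels and field-of-view (FOV) structure are the common currency.

## The statistics

- **Niche detection.** Each cell *i* is represented by the composition vector
  `c_i ∈ Δ^{T−1}`, the type fractions of its *k* nearest same-FOV neighbours
  (Euclidean µm, self excluded, default k = 20). Niches are k-means clusters
  of the `c_i` (default 7), numbered by descending size. Pathway genes are
  confirmed in a niche by a one-sided Wilcoxon rank-sum on CP10K·log1p
  expression, BH-corrected.
- **Proximity.** For ordered types (A, B), `obs_freq(A,B)` is the fraction of
  A cells whose single nearest neighbour is type B. A within-FOV label
  permutation gives null moments, `z = (obs − μ₀)/σ₀`, `p = 1 − Φ(z)`, and
  BH `q` over all ordered pairs; average-linkage clustering of the
  symmetrized z cuts the types into co-localization groups (default 6).
- **Abundance.** Pooled proportions per group; `log2FD` with a Haldane 0.5
  correction only when a count is zero; p from 10,000 cell-level group-label
  permutations and a two-sided Fisher exact test; a type is enriched when
  BH FDR < 0.01 and |log2FD| > 0.58 (strict).
- **Association.** Pearson iff both vectors pass Shapiro–Wilk at α = 0.05,
  else Spearman; flags at |r| > 0.5, unadjusted P < 0.05.
- **Signaling.** `strength(s→t, L, R) = scaled(L,s) · scaled(R,t)` with
  per-gene min-max scaling of state means; permutation p from state-label
  shuffles; within-niche restriction keeps pairs whose sender and receiver
  each hold ≥ 2% of a niche's cells.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```sh
synovniche simulate --seed 7 --n-cells 20000 --out demo/
synovniche niches --cells demo/cells.csv --k 20 --n-niches 7 --seed 7 --out demo/
synovniche proximity --cells demo/cells.csv --n-perm 1000 --seed 7 --out demo/
```

or, in Python, recovery of the planted niche structure end to end:

```python
>>> from synovniche import benchmarks
>>> round(benchmarks.niche_recovery_ari(seed=0), 4)   # 20,000 cells, 7 bands niches
0.8425
>>> [round(v, 4) for v in benchmarks.proximity_calibration(seed=0)[:2]]
[0.0212, 0.0]   # iid labels: mean z, fraction of pairs at q <= 0.05
```

The first number is the adjusted Rand index between planted and detected
niches (1.0 = perfect partition recovery; ≥ 0.8 means the seven planted
strata are essentially recovered up to boundary cells). The calibration pair
shows the permutation z is centred (mean ≈ 0) and that no type pair reaches
q ≤ 0.05 when labels are exchangeable — the null behaves as a null.

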