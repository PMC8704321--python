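# ltpoly

Ternary ligand–target activity relations: data completeness and
interval-valued polypharmacology.

## The problem

Large bioactivity panels (kinase profiling matrices, ChEMBL extracts) are
mostly *unmeasured*: for a typical ligand, only a fraction of the targets in
the panel have ever been assayed against it. Treating unmeasured pairs as
inactive — the default in many analyses — silently converts absence of
evidence into evidence of absence. `ltpoly` keeps the third state explicit.
Every (ligand, target) pair carries exactly one of three states:

- **active** (`a+`) — the pair was measured and passed the activity cutoff,
- **inactive** (`a−`) — measured and failed the cutoff, or annotated "not active",
- **null** (`a∅`) — never determined.

The full assignment is a ternary relation ℛ(L, T, A) whose three state
classes partition the L × T grid. From it the package computes:

- **Data completeness.** Global data completeness
  GDC = (#active + #inactive) / (|L|·|T|), and its local analogues
  LDC(l) = (|S+(l)| + |S−(l)|)/|T| per ligand and LDC(t) per target, with
  empirical CDFs. The per-ligand and per-target means of LDC both equal GDC
  exactly — an identity the package verifies on every report.
- **Simple polypharmacology.** The number of targets a ligand truly hits,
  P(l), is only interval-known: Pmin(l) = |S+(l)| ≤ P(l) ≤ Pmax(l) =
  |S+(l)| + |S∅(l)|. An urn-model probability
  p̂ = |S+| / (|S+| + |S−|) — the active fraction among the ligand's
  *measured* pairs — shrinks the upper bound to the expectation value
  P̃max(l) = |S+| + p̂·|S∅|, with a Jeffreys Bayesian interval on p̂ mapped
  affinely onto the count scale as a confidence interval.
- **Joint polypharmacology.** For a ligand pair, the 3 × 3 cross-tabulation
  of states over T partitions the target set; Pmin(l,l′) = |S+,+|,
  Pmax(l,l′) adds the three cells where neither ligand is known inactive,
  and cellwise urn probabilities (or a product-of-marginals independence
  assumption) give the shrunken estimate P̃max(l,l′), with a seeded
  Monte Carlo confidence interval.
- **Thresholding.** Raw Kd/Ki (molar) or pKd/pKi measurements are converted
  to active/inactive calls at a 3 µM (pK 5.5) cutoff; conflicting calls for
  one pair yield **null**, never a majority vote.
- **Synthetic data.** A generator with known ground truth (per-ligand
  activity rates, MCAR or blockwise "islands of data" observation, optional
  publication bias) backs recovery tests of all the estimators.

Intended users: cheminformaticians and drug-discovery data scientists who
need honest promiscuity estimates from incomplete panels.

## Worked example

A two-ligand, five-target dataset: `l1` is active on `t1,t2`, inactive on
`t3`; `l2` active on `t2,t4`, inactive on `t5`; the other four pairs were
never measured.

```sh
$ ltpoly validate toy.tsv
ligands 2
targets 5
active  4
inactive        2
null    4
gdc     0.600000
```

Six of ten pairs are known, so GDC = 0.6. Per-ligand estimates:

```sh
$ ltpoly polypharm toy.tsv --out pp.tsv && cat pp.tsv
id  n_active  n_inactive  n_null  p_min  p_hat         p_hat_source     p_tilde_max  ci_low       ci_high      p_max
l1  2         1           2       2      0.6666666667  ligand-specific  3.333333333  2.353472194  3.922504764  4
l2  2         1           2       2      0.6666666667  ligand-specific  3.333333333  2.353472194  3.922504764  4
```

`l1` is known-active on 2 targets (Pmin), could be active on up to 4
(Pmax); its measured active fraction is 2/3, so the expected
polypharmacology is 2 + (2/3)·2 = 10/3 ≈ 3.33, with a 95% Jeffreys interval
[2.35, 3.92] on the count scale. The joint estimate for the pair:

```sh
$ ltpoly joint toy.tsv --out j.tsv --seed 1 && cat j.tsv
id1  id2  n_pp  n_pm  n_p0  n_mp  n_mm  n_m0  n_0p  n_0m  n_00  p_min  p_tilde_max_joint  p_tilde_max_indep  ci_low       ci_high     p_max
l1   l2   1     0     1     0     0     1     1     1     0     1      3                  2.333333333        1.694907923  2.98125872  3
```

Both ligands are known-active on 1 shared target (Pmin = 1) and could share
up to 3 (Pmax). Under the independence assumption the expected joint
polypharmacology is 1 + (2/3) + (2/3) = 7/3 ≈ 2.33.

The same analyses run from Python: `ltpoly.build_relation`, `ltpoly.gdc`,
`ltpoly.completeness_report`, `ltpoly.polypharm_report`,
`ltpoly.joint_report`, `ltpoly.SyntheticSpec` / `ltpoly.generate` /
`ltpoly.recovery_trial`.

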