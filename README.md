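# screenopt

Optimal design of multi-arm screening trials within a drug development
program.

## The problem

A sponsor with a long pipeline of candidate treatments runs small
*screening* trials to decide which candidates deserve a large
*confirmatory* (phase III) trial, and keeps screening new candidates until
one finally succeeds at phase III.  How many arms should a screening trial
carry, how many patients per arm, and how promising must an arm look
before a confirmatory trial is launched?

`screenopt` answers these questions by minimizing the **expected sample
size until the first phase III success (ESS)** — the expected total number
of patients recruited, across repeated screening + confirmatory cycles, up
to and including the first successful confirmatory trial.  It is aimed at
trial statisticians planning screening programmes (public funders, platform
trials, dose/combination screens) rather than a single two-arm study.

## Model

Each screening trial allocates `n1` patients to each of `K` experimental
arms and a shared control; responses are normal with unit variance
(effects standardized) and the candidates' true standardized effects are
exchangeable draws from a prior `N(m0, v0²)`.  With z-statistics
`Z_i` comparing arm *i* to control, two progression rules are supported:

* **top-treatment** — the best arm proceeds to a two-arm confirmatory
  trial iff `max Z_i > c1`;
* **all-interesting** — every arm with `Z_i > c1` proceeds to one
  multi-arm confirmatory trial (Dunnett-type family-wise error control,
  per-arm size set for marginal power `1−β` at the clinically relevant
  difference `δ`).

Confirmatory trials may be single-stage or group-sequential with
triangular stopping boundaries (including multi-arm multi-stage, MAMS).
Because cycles are independent and identically distributed, the renewal
identity gives

```
ESS = E[patients per cycle] / P(cycle ends in phase III success)
```

and both ingredients reduce to one- or two-dimensional normal integrals
(or, for MAMS confirmatory trials, common-random-number simulation on a
reusable dataset bank).  A Nelder–Mead search with integer refinement
optimizes `(n1, c1)` per `K` and scans `K`.

## Worked example

ESS and screening operating characteristics of a 9-arm screening design
with 22 patients per arm, threshold −0.429, under the reference scenario
(`m0 = 0`, `v0 = 0.1`, `δ = 0.25`, one-sided `α = 0.025`, power 0.9):

```
$ screenopt evaluate --k 9 --n1 22 --c1 -0.429 --m0 0 --v0 0.1 --delta 0.25
ESS      3805.4
E[P1]    0.9715
E[P2]    0.2295
FWER     0.965
power    0.412
```

Read: each cycle screens 220 patients; with probability 0.97 a
confirmatory trial (673 further patients) is launched and with probability
0.23 the cycle ends in a confirmed treatment, giving an expected 3 805
patients until the programme's first phase III success.  The screening
stage triggers a confirmatory trial with probability 0.965 even when all
nine effects are null (an intentionally lax screen — the confirmatory
trial carries the error control), and selects a truly effective arm
(`μ = 0.25`, others null) with probability 0.412.

Optimizing instead of evaluating:

```
$ screenopt optimize --k-min 1 --k-max 15 --out scan.csv
best: K=9 n1=22 c1=-0.428 ESS=3805
```

The same computations are available as library calls
(`ess_top_single`, `ess_all_interesting`, `ess_top_groupseq`, `ess_mams`,
`optimize_design`, `scan_K`, `simulate_ss_quantile`); see the module
docstrings and `docs/methods.md`.

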