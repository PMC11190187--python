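# prosodecode

Tools for asking whether prosody shapes the neural processing of syntax
during natural listening. When a speaker closes a syntactic phrase, the
acoustic signal often carries a *prosodic boundary* — a pause, pitch
reset, or syllable lengthening. `prosodecode` implements a complete
analysis pipeline that (1) quantifies how strongly closing phrase
boundaries and prosodic boundary strength co-occur in speech stimuli, and
(2) asks, via cross-condition decoding of multichannel brain recordings,
whether the neural representation of a closing phrase boundary is
*enhanced* when prosody and syntax agree.

Because the kind of data this targets (MEG recorded during natural
listening) is typically restricted, the package ships a first-class
synthetic-data module that generates word tables and multi-subject
recordings with the same statistical structure, so every stage — and the
full pipeline — runs and is tested at desk scale with no data download.

## The analysis

**Stimulus model.** Per-word prosodic boundary strength `s > 0` is
right-skewed and is modelled as a two-component gamma mixture

    p(s) = w1 Gamma(s; k1, r1) + w2 Gamma(s; k2, r2),

fitted by EM (weighted gamma MLE per M-step, Newton iteration on the
digamma equation). Words are binarized weak/strong at the density
crossing `w1 f1(s*) = w2 f2(s*)` between the component means — the point
of equal posterior membership. The prosody–syntax association is then
tested with a binomial GLM (closing-boundary label ~ prosody class) and a
Gamma GLM with inverse link (strength ~ closing label).

**Syntax labels.** From PTB-style bracketed constituency trees, each word
receives its closing-node count — the number of tree nodes whose
rightmost terminal it is, equal to the run of `)` after the word in the
bracket string. Words closing more than one node carry a closing phrase
boundary; words closing only their own preterminal do not.
Out-of-dictionary tokens, sentence-final words, and zero-strength words
are excluded.

**Decoding.** A logistic classifier is trained to read the closing-phrase
label from epoched, SVD-reduced recordings, using *only* weak-prosody,
class-balanced tokens (the neutral pool), so the decoder itself is free
of prosodic bias. Generalization is measured as AUC on three balanced
test sets: **neutral** (weak prosody only), **coherent** (the
combinations that statistically co-occur: strong∧closing, weak∧no
closing), and **incoherent** (the mismatched combinations). Two readouts:
whole-window MVPA (400 ms pre- and post-offset windows, C = 1, tenfold
randomized CV) and per-timepoint temporal decoding (nested fivefold CV
over a log-spaced C grid from 1e-5 to 1e5).

**Group statistics.** Per-condition AUCs are tested against the 0.5
chance level and against each other by paired sign-flip permutation tests
(2048 permutations — exhaustive for eleven subjects, since 2^11 = 2048)
with Bonferroni–Holm correction; temporal AUC series by a cluster-based
permutation test (pointwise one-sample t, cluster mass, max-statistic
sign-flip null); and replicability at the individual level by Bayesian
population prevalence: with `k` of `n` subjects individually significant
at level α, under θ = α + γ(1−α) and a uniform prior the posterior on θ
is Beta(k+1, n−k+1), giving MAP(γ) = max(0, (k/n − α)/(1 − α)) and a 95%
highest-posterior-density interval mapped back to γ.

## Worked example

```python
import numpy as np
from prosodecode import (SynthConfig, gen_word_table, fit_gamma_mixture,
                         mixture_boundary, classify_strength, test_association,
                         prevalence_estimate)

cfg = SynthConfig(n_words=20000, seed=0)       # planted P(closing|strong)=0.72, P(closing|weak)=0.44
table = gen_word_table(cfg)
fit = fit_gamma_mixture(table["strength"].to_numpy(), rng=0)
b = mixture_boundary(fit)
print(f"component 1: shape={fit.shape[0]:.2f} rate={fit.rate[0]:.2f}")
print(f"component 2: shape={fit.shape[1]:.2f} rate={fit.rate[1]:.2f}")
print(f"weak/strong boundary at strength {b:.2f}")

table["prosody_class"] = classify_strength(table["strength"].to_numpy(), b)
res = test_association(table)
print(f"binomial GLM closing ~ prosody: z={res.binomial_z:.2f}, p={res.binomial_p:.2e}")

prev = prevalence_estimate(k=11, n=11, alpha=0.05)
print(f"prevalence MAP={prev.map:.2f}, 95% HPDI=[{prev.hpdi[0]:.2f} {prev.hpdi[1]:.2f}]")
```

prints

```
component 1: shape=1.08 rate=2.64
component 2: shape=15.29 rate=11.71
weak/strong boundary at strength 0.95
binomial GLM closing ~ prosody: z=23.71, p=2.78e-124
prevalence MAP=1.00, 95% HPDI=[0.77 1.00]
```

The EM recovers the generating components (shapes 1.1 and 14, rates 2.8
and 10.7) from the sample; the boundary splits the words into weak/strong
prosody classes; the binomial GLM confirms the planted association
(closing boundaries are more frequent under strong prosody). A prevalence
MAP of 1.00 with HPDI [0.77, 1.00] says that if all 11 subjects show a
within-subject effect at α = 0.05, the population prevalence of the
effect is credibly at least 0.77.

The full pipeline runs from the command line:

```bash
prosodecode run-all --seed 11 --outdir results/run --no-temporal
```

On the default 11-subject synthetic cohort this reports post-offset group
mean AUCs of 0.85 (coherent) > 0.78 (neutral) > 0.72 (incoherent) — the
planted coherence enhancement — with all three above chance and both
coherent-vs-other contrasts significant under the exhaustive sign-flip
permutation test. Individual stages are available as `simulate`,
`fit-mixture`, `label-syntax`, `build-sets`, `epochs`, `decode`, and
`stats` subcommands reading and writing CSV/HDF5/JSON.

## Layout

- `src/prosodecode/synth.py` — synthetic word tables, recordings, cohorts
- `src/prosodecode/prosody.py` — gamma-mixture EM, binarization, association GLMs
- `src/prosodecode/syntax.py` — bracketed trees, closing-node counts, token filters
- `src/prosodecode/sets.py` — balanced training pool and generalization sets
- `src/prosodecode/epochs.py` — offset-locked epoching, SVD reduction
- `src/prosodecode/decode.py` — window MVPA and temporal decoding
- `src/prosodecode/stats.py` — permutation, cluster, and prevalence inference
- `src/prosodecode/pipeline.py`, `cli.py` — orchestration and subcommands
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
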