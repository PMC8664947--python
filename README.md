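# hypnostats

Super-statistical analysis of sleep EEG: per-epoch hyper-parameter
extraction, Bayesian sleep staging with a Markov prior, within-phase
trend analysis, Markov hypnogram simulation, and cluster-separability
measures — with a built-in synthetic EEG generator so the whole chain is
testable without clinical recordings.

## The problem

Clinically, human sleep is scored into discrete stages (Wake, REM, N1,
N2, N3) from 30-second EEG epochs.  An alternative view treats the raw
single-channel EEG signal as a **heterogeneous random walk**: a
stochastic process whose governing parameters are themselves slowly
time-dependent.  Under this view each epoch `n` and channel `k` is
summarized not by wave-form features but by statistical
**hyper-parameters** of the amplitude distribution:

* `STD_{n,k} = sqrt(<(y - ȳ)²>)` — amplitude scale (µV),
* `KUR_{n,k} = <((y - ȳ)/σ)⁴> - 3` — excess kurtosis (tail weight),
* `SKE_{n,k} = <((y - ȳ)/σ)³>` — skewness,
* `ACF300` — the autocorrelation `A(Δt) = <(y_t - ȳ)(y_{t+Δt} - ȳ)>/σ²`
  at a lag of 300 ms,

all with population (divide-by-N) normalization.  These
hyper-parameters have characteristic, stage-dependent distributions
`q(h | s)`, carry linear trends within contiguous same-stage *sleep
phases*, and the stage sequence itself is well described by a
first-order Markov chain `M(s_{n+1} | s_n)`.

The package turns these observations into tools:

* **Bayesian stage filter** — forward update
  `P(s_n) ∝ Q(D_n | s_n) · Π(s_n)` with the Markov-propagated prior
  `Π(s_n) ∝ Σ_{s_{n-1}} M(s_n | s_{n-1}) P(s_{n-1})` and the likelihood
  `Q = Π_k q(h_{kn} | s_n)` over a chosen hyper-parameter subset.
  On artifact epochs only the prior is used.
* **Trend analysis** — ordinary least-squares slope `a_J` of each
  hyper-parameter within each sleep phase `J`, aggregated per stage
  with REM/N1/N2 split into the falling (towards N3) and rising
  (towards Wake) parts of the sleep cycle.
* **Separability** — the General Discrimination Value (GDV: mean
  intra-class minus mean inter-class distance on z-scored-and-halved
  coordinates, scaled by `1/√D`) and the Cluster Separation Index
  (CSI: mean log-ratio of nearest other-class to nearest same-class
  neighbor distance), applied pairwise to the stage clusters in
  (STD, KUR, SKE) space.
* **Synthetic generator** — a two-level surrogate: a Markov chain
  produces the hypnogram; within each epoch an AR(1) process with
  heavy-tailed (Student-t), optionally skewed innovations and
  block-wise log-normal variance modulation produces the signal.  Its
  statistics are known in closed form, which makes every estimator
  testable.

## Worked example

```python
import hypnostats as hs

# a full synthetic night: 240 epochs, 3 channels, 2% artifact epochs
cfg = hs.GeneratorConfig(n_epochs=240, seed=1, artifact_rate=0.02)
rec, hyp, truth = hs.generate_recording(cfg)

tab = hs.hyperparameter_table(rec, hyp)
print(tab.head(3))
#  epoch  channel stage       STD      KUR       SKE    ACF300  artifact
#      0        0  Wake 31.980453 0.654971  0.228251 -0.024023     False
#      0        1  Wake 34.443760 0.193358 -0.000043  0.047608     False
#      0        2  Wake 35.629504 1.327095  0.427545  0.040960     False

pooled = hs.pool_hyperparameters(tab)
print({s: round(float(v["STD"].mean()), 1) for s, v in pooled.items()})
# {'Wake': 33.4, 'REM': 91.5, 'N1': 225.1, 'N2': 598.9, 'N3': 1784.6}

# fit likelihoods and the Markov prior on an independent night,
# then stage the first recording with the Bayesian filter
rec2, hyp2, _ = hs.generate_recording(hs.GeneratorConfig(n_epochs=240, seed=2))
tab2 = hs.hyperparameter_table(rec2, hyp2)
model = hs.fit_stage_likelihoods(hs.pool_hyperparameters(tab2))
M = hs.epoch_transition_matrix([hyp2], smoothing=0.5)
post = hs.infer_sequence(tab, model, M)          # STD, KUR, SKE factors
print(round(hs.accuracy(post.map_labels, hyp), 3))
# 0.992
```

The per-stage mean STD reproduces the generator's amplitude ladder
(Wake lowest, N3 highest), and with stage-disjoint amplitude scales the
held-out filter recovers 99% of the scored epochs.  The |GDV| stage
distance matrix from the same table (`hs.stage_distance_matrix(tab)`)
is symmetric with zero diagonal, larger for stage pairs that are
further apart in amplitude.

The same chain is available from the shell:

```bash
hypnostats generate --n-epochs 240 --seed 1 --out-dir night1
hypnostats stats night1/recording.txt night1/hypnogram.txt \
    --mask night1/mask.txt --out night1/hyper.tsv
hypnostats run --seed 1 --out-dir full_run     # everything in one go
```

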