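# sadnet

Graph-theoretic analysis of emotion–cognition brain networks from ROI
BOLD time series: signed functional connectivity, community structure,
connector-hub identification, and paradigm × sadness-intensity
interaction statistics — plus a synthetic cohort generator that makes
the entire chain testable without access to recorded fMRI data.

The scientific question: when a strong emotional state (provoked
sadness) precedes a cognitive task (spatial working memory), which
network nodes mediate the interaction between the dorsal, cognition-
related subnetwork (dlPFC, IPS, iFG, mSFG, PCG) and the ventral,
emotion-related subnetwork (sACC, mFP, mOFG, amygdala, hippocampus)?
The package is written for researchers who have per-subject,
per-paradigm ROI time-series matrices (TSV) — or who want a fully
synthetic but statistically faithful stand-in — and need the standard
analysis chain with explicit, tested contracts.

## The model in brief

Edges are Pearson correlations between conditioned ROI signals
(linear detrend → common-signal regression → zero-phase band-pass,
0.018 Hz up to just below Nyquist).  Communities maximize the
signed-modularity quality function with separate resolution parameters
for positive and negative weights,

    Q = (1/v⁺) Σᵢⱼ (w⁺ᵢⱼ − γ⁺e⁺ᵢⱼ) δ(cᵢ,cⱼ) − (1/(v⁺+v⁻)) Σᵢⱼ (w⁻ᵢⱼ − γ⁻e⁻ᵢⱼ) δ(cᵢ,cⱼ),

optimized by seeded greedy local moves + merges (exact on all
exhaustively enumerable test graphs).  Node metrics are binary degree
k and participation coefficient P = 1 − Σₛ(k_s/k)² on graphs
thresholded at a fraction of each subject's maximal |r| (fraction
selected by maximizing across-node degree variance).  Connector hubs
have degree > mean + 1 SD and participation above the mean.  Effects of
interest are paradigm × group interactions in a subject-blocked mixed
ANOVA with BH-FDR over edges and permutation tests (add-one p) for
group differences.  Details: [docs/methods.md](docs/methods.md).

## Worked example

```python
from sadnet import (default_ground_truth, simulate_cohort, preprocess_set,
                    correlation_matrix, group_mean_matrix, detect_communities,
                    select_threshold, node_metrics, identify_hubs, PARADIGMS)

spec = default_ground_truth()          # planted dorsal/ventral structure
cohort = simulate_cohort(spec, seed=1)  # 22 subjects, 2x160 volumes at TR=2s

mats = {p: [correlation_matrix(preprocess_set(s.timeseries[p]))
            for s in cohort.subjects] for p in PARADIGMS}
for p in PARADIGMS:
    mean = group_mean_matrix(mats[p])
    res = detect_communities(mean, gamma_pos=1.0, gamma_neg=0.45, seed=1)
    thr, _ = select_threshold(mats[p])
    hubs = identify_hubs(node_metrics(mats[p], res.partition, thr),
                         paradigm=p, seed=1)
    print(p, round(res.Q, 3), thr, hubs.hubs)
```

prints

```
Neutral-WM1 0.634 60.0 ['dlPFCl', 'mFPl']
Sadness-WM2 0.636 50.0 ['dlPFCl', 'mFPl']
```

i.e. both paradigms split into the planted dorsal and ventral
communities (Q slightly higher after sadness induction — more
segregation), and the two planted connector hubs — left dorsolateral
prefrontal cortex and left medial frontal pole — are flagged: their
mean degree exceeds the network mean by more than one SD and their
participation coefficient is above the network mean.  The scripts in
`examples/` walk through each capability (cohort simulation and
behavioral scoring, preprocessing and edge-group summaries, communities
and hubs, hub-edge interaction statistics) and print annotated numbers;
`sadnet simulate`/`sadnet run` expose the same pipeline on the command
line.

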