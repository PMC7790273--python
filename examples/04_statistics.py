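"""The statistical layer: ratings contrasts, chance-level tests, weight maps.

Each family carries its own Bonferroni correction: m=12 for the rating
contrasts, m=120 for accuracy-vs-chance tests, m=64 for mood correlations.
"""

import numpy as np

import fnirsdecode as fd
from fnirsdecode.decode import _comparison_slice

rng = np.random.default_rng(2)

# 1. subjective ratings: positive vs negative valence, 20 subjects per draw
pos = [fd.generate_ratings("reactive", "positive", rng)[0] for _ in range(20)]
neg = [fd.generate_ratings("reactive", "negative", rng)[0] for _ in range(20)]
r = fd.two_sample_t_ratings(pos, neg, name="reactive valence pos-vs-neg")
print(f"valence contrast: t={r.statistic:.2f}, p_bonf={r.p_bonferroni:.2e} "
      f"(m={r.m_corrections}, significant={r.significant})")

# 2. decoding accuracies vs the 50% chance level
params = fd.scaled_params(8, 4, seed=21)
train, test = fd.simulate_feature_tables(params)
res = fd.cross_dataset_evaluate(train, test, "pos_vs_neu", "active",
                                fractions=[0.05])
accs = [x.balanced_accuracy_pct for x in res]
t = fd.one_sample_t_vs_chance(accs)
print(f"accuracy vs chance: mean {np.mean(accs):.2f}%, t={t.statistic:.2f}, "
      f"p_bonf={t.p_bonferroni:.3g} (m={t.m_corrections})")

# 3. signed LDA weights of the selected features, mapped to scalp regions
X, y, _, cols, classes = _comparison_slice(train, "pos_vs_neu", "active")
sel = fd.rank_features(X, y, classes=classes).order[:3]
model = fd.fit_lda(X[:, sel], y, classes=classes,
                   feature_names=[cols[i] for i in sel])
weights = fd.summarize_weights(model, fd.default_montage())
print(weights.to_string(index=False))
print("Opposed weight signs reflect the opposed planted directions: positive")
print("trials raise dHbR on 6-7, neutral trials raise it on 5-4 and 4-4.")

# 4. mood correlations are null by construction
pre = rng.integers(0, 11, size=(len(accs), 16)).astype(float)
post = rng.integers(0, 11, size=(len(accs), 16)).astype(float)
mood = fd.spearman_mood(accs, pre, post)
n_sig = sum(m.significant for m in mood)
print(f"mood correlations: {len(mood)} tests, {n_sig} significant after "
      f"Bonferroni (m={mood[0].m_corrections})")
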