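"""The two-sound attention battery and the prospective power analytics.

Simulates the cocktail-party design (24 cross-category pairs, each heard
under both attention conditions), decodes features from the mixture
responses, scores each trial by majority vote over its three windows, and
tests the 48 binary outcomes against chance with an exact binomial test.
Also prints the two design sample sizes the statistics rest on.
"""

import numpy as np

from neurosound import benchmark as bm
from neurosound import decoding, evaluation, synth

seed = 1
bench = bm.make_benchmark(seed, profile="generator",
                          noise_sd=bm.DEFAULT_NOISE_SD, fit_generator=False)

pool = []
for cat in synth.CATEGORIES:
    pool.extend([s for s in bench.stimuli_test if s.category == cat][:2])
trials = synth.make_attention_design(pool, seed=seed)
print(f"{len({t.id for t in trials})} pairs, {len(trials)} attention trials")

maps = {s.id: m for s, m in zip(bench.stimuli_test, bench.maps_test)}
rng = np.random.default_rng(seed + 100)
window_scores = {}
for trial in trials:
    scores = []
    for w in range(3):
        ua = maps[trial.attended_stim.id][w][1].reshape(-1)
        uu = maps[trial.unattended_stim.id][w][1].reshape(-1)
        x = bench.W @ (ua + 0.3 * uu) + \
            (bm.DEFAULT_NOISE_SD / np.sqrt(8)) * rng.standard_normal(
                bench.W.shape[0])
        yhat = bench.decoder.predict_matched(x, n_trials=8)
        scores.append(evaluation.attention_window_score(yhat, ua, uu))
    window_scores[f"{trial.id}#{trial.attended}"] = scores
outcomes, stat = evaluation.attention_evaluate(window_scores)
print(f"attended-sound identification: {stat.mean:.3f} "
      f"(binomial p = {stat.p_value:.4f}, n = {len(outcomes)})")

n_t = evaluation.required_n_ttest(d=0.5, alpha=0.05, power=0.80)
n_b = evaluation.required_n_binomial(p1=0.7, p0=0.5, alpha=0.05, power=0.80)
print(f"required N, one-sided t-test at d = 0.5: {n_t}")
print(f"required N, exact binomial 0.7 vs 0.5:  {n_b}")

# Attended-sound identification sits modestly above chance and does not
# always reach significance at this noise level — attentional selection
# with a 0.3 leak of the unattended stream is a weak effect, which is why
# the design sizes matter: 48 trials exceed the 37 needed to detect a 0.7
# correct rate, and the 50-stimulus test set exceeds the 27 needed for a
# medium effect.
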