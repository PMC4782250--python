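"""Standardized-regression sensitivity analysis for each consumption model.

Each parameter independently takes its mean or mean +/- 10% per iteration;
standardized consumption is regressed on the standardized inputs.  The
coefficient magnitudes rank parameter influence: the metabolic-rate
intercepts (log_s, log_r) and the temperature coefficient (Q10) dominate
their models, mass (W) and assimilation (A) act negatively, and the growth
parameters (Gv, Fj) barely matter.
"""

from bioenergize import MODELS, load_registry, sensitivity_analysis

registry = load_registry()
for i, model in enumerate(MODELS):
    rep = sensitivity_analysis(registry, model, n=10_000, seed=10 + i)
    top = ", ".join(f"{s} {c:+.3f}" for s, c in rep.ranked()[:4])
    print(f"{model:>6} (R2 = {rep.r_squared:.3f}): {top}, ...")
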