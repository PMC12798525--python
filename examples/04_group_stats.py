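"""Group statistics on a simulated cohort's feature table.

Runs the one-way pupil ANCOVA (age-adjusted), the repeated-measures
ANCOVA of entropy profiles (Greenhouse-Geisser corrected), post hoc
per-scale t-tests with FDR, and the Fisher-z power calculation.
"""

import numpy as np

from oculomse import (
    ancova_oneway,
    posthoc_scale_ttests,
    required_sample_size_correlation,
    rm_ancova_group_by_scale,
)

rng = np.random.default_rng(0)
n_td, n_adhd, k = 20, 16, 30
groups = np.array(["TD"] * n_td + ["ADHD"] * n_adhd)
age = rng.uniform(20, 50, n_td + n_adhd)

# synthetic log-FuzzyEn profiles with a built-in deficit at fine scales
profiles = rng.normal(-1.0, 0.25, (n_td + n_adhd, k))
profiles[n_td:, :12] -= 0.35
pupil = np.r_[rng.normal(4.0, 0.4, n_td), rng.normal(4.4, 0.4, n_adhd)]

anc = ancova_oneway(pupil, groups, age)
print(f"pupil ANCOVA: F={anc.F:.3f}, p={anc.p:.4f}, partial eta^2={anc.eta_sq:.3f}")

res = rm_ancova_group_by_scale(profiles, groups, age)
for name in ("group", "group_x_scale"):
    r = res[name]
    eps = f", GG eps={r.gg_epsilon:.3f}" if r.gg_epsilon else ""
    print(f"rm-ANCOVA {name}: F={r.F:.3f}, p={r.p:.4f}, eta^2={r.eta_sq:.3f}{eps}")

tests = posthoc_scale_ttests(profiles, groups)
flagged = [t.scale for t in tests if t.flag05]
print(f"post hoc t-tests: scales flagged at q<0.05: {flagged}")

power = required_sample_size_correlation(r=0.36, alpha=0.05, power=0.80)
print(
    f"n to detect |r|=0.36 at 80% power: {power['n_ceiling']} "
    f"(~{power['n_nearest_ten']})"
)
# The flagged scales recover the injected fine-scale deficit; the power
# line shows why a 16-participant group cannot confirm a modest correlation.
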