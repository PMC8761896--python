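"""Compare two antibody variants by their per-snapshot feature distributions.

Two 300-frame synthetic ensembles differ only in the mean of the HL torsion
(a planted +5 degree shift, spread 2 degrees).  The KS test with Bonferroni
control across the six orientation parameters must flag HL and nothing else.
"""

from fabkit import apply_domain_map, compare_variants, feature_series_multi
from fabkit.synth_fixtures import ToyFabSpec, make_toy_fab

FEATURES = ["HL", "HC1", "HC2", "LC1", "LC2", "dc"]


def ensemble(seed, mu):
    structure, domain_map, _ = make_toy_fab(
        ToyFabSpec(n_frames=300, seed=seed, fv_only=True, hl_twist=("gaussian", mu, 2.0))
    )
    return feature_series_multi(
        apply_domain_map(structure, domain_map), FEATURES, window=(0.0, 1.0)
    )


variant_a = ensemble(seed=21, mu=0.0)
variant_b = ensemble(seed=22, mu=5.0)
report = compare_variants(variant_a, variant_b, alpha=0.01)

print(f"Bonferroni across m={report.m} features, per-test threshold {report.threshold:.2e}")
print(f"{'feature':8} {'D':>7} {'p':>10} {'median diff':>12}  stars")
for f in report.features:
    print(
        f"{f.feature:8} {f.ks.D:7.3f} {f.ks.p:10.3g} {f.median_difference:12.3f}  {f.stars}"
    )

# "**" marks corrected significance at alpha=0.01, "*" uncorrected p<0.05,
# "ns" otherwise.  Only HL carries the planted shift; its median difference
# recovers the applied +5 degrees.
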