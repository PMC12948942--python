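"""Shared settings for the analysis drivers.

One synthetic cohort stands in for the access-restricted registry data:
n families of genotyped mother-father-offspring trios, distress measured
over three lockdown waves, sibling clusters, and polygenic scores for the
five psychiatric traits.  Sizes are desk-scale; the replicated validation
experiments live in the test suite and scripts/acceptance.py.
"""

from pathlib import Path

from triofx.params import VCParams
from triofx.simulate import SimConfig

SEED = 1
_ROOT = Path(__file__).resolve().parent.parent
RESULTS = _ROOT / "results"  # small summary tables
RUN_DIR = _ROOT / "scratch" / "cohort"  # bulky regenerable intermediates

# adolescent scenario: direct 8.8%, maternal indirect 10.4% of variance,
# slight negative direct-maternal correlation
TRUTH = VCParams(sigma2_o=0.088, sigma2_m=0.104, sigma_om=-0.013, sigma2_e=0.82)

COHORT = SimConfig(
    n_families=600,
    n_snps=800,
    truth=TRUTH,
    focal_role="offspring",
    n_timepoints=3,
    sibling_fraction=0.08,
    seed=SEED,
)

# GRM noise is ~1/sqrt(M); the unrelatedness cutoff must sit above it at
# this SNP count while still catching the duplicate-mother sibling pairs
UNRELATED_THRESHOLD = 0.25
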