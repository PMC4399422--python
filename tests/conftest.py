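import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from antioxcap import InhibitionCurve  # noqa: E402


def make_curve(ic50, h=1.0, concs=None, noise_sd_abs=0.0, n_replicates=3,
               rng=None, assay_id="ABTS", solute="synthetic", control=0.750):
    """Synthetic inhibition curve straight from the Hill response.

    Absorbance noise of ``noise_sd_abs`` AU on a control window of
    ``control`` AU translates to inhibition noise of 100*sd/control %.
    """
    if concs is None:
        concs = np.geomspace(ic50 / 10, ic50 * 10, 8)
    concs = np.asarray(concs, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for rep in range(1, n_replicates + 1):
        inh = 100.0 * concs**h / (concs**h + ic50**h)
        if noise_sd_abs > 0:
            inh = inh + rng.normal(0, 100.0 * noise_sd_abs / control, size=concs.shape)
        for c, i in zip(concs, inh):
            rows.append((c, i, rep))
    return InhibitionCurve(
        assay_id=assay_id, solute=solute,
        points=pd.DataFrame(rows, columns=["conc", "inhibition", "replicate_id"]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
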