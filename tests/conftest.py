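import numpy as np
import pandas as pd
import pytest

from restspectra.data import EpochSet, OCCIPITAL
from restspectra.stats import make_feature_table

OCC = list(OCCIPITAL)


def sine_epochs(freq=10.0, amp=1.0, srate=256.0, n_epochs=8,
                channels=("O1",), condition="EC", length=2.5,
                phase=0.0) -> EpochSet:
    """Epochs of a pure sinusoid, identical across epochs and channels."""
    t = np.arange(int(length * srate)) / srate
    sig = amp * np.sin(2 * np.pi * freq * t + phase)
    data = np.tile(sig, (n_epochs, len(channels), 1))
    return EpochSet(data, np.array([condition] * n_epochs), srate,
                    list(channels), length)


def noise_epochs(rng, srate=256.0, n_epochs=20, channels=("O1",),
                 condition="EO", length=2.5) -> EpochSet:
    data = rng.standard_normal((n_epochs, len(channels),
                                int(length * srate)))
    return EpochSet(data, np.array([condition] * n_epochs), srate,
                    list(channels), length)


def covariate_frame(n, seed=0, n_sites=3, balanced=True) -> pd.DataFrame:
    """Random covariate table with both groups at every site."""
    r = np.random.default_rng(seed)
    sites = [chr(ord("A") + i) for i in range(n_sites)]
    if balanced:
        group = np.repeat(["ASD", "NT"], (n + 1) // 2)[:n]
    else:
        group = r.choice(["ASD", "NT"], n)
    return pd.DataFrame(dict(
        id=[f"s{i:03d}" for i in range(n)],
        group=group,
        age=r.uniform(6, 32, n),
        sex=r.choice(["M", "F"], n, p=[0.72, 0.28]),
        iq=np.clip(r.normal(106, 14, n), 76, None),
        site=np.tile(sites, n // n_sites + 1)[:n],
        medication=r.random(n) < 0.2,
    ))


def simulated_feature_table(n=200, seed=0, beta_group=0.0, delta=1.0,
                            site_sd=0.3, noise_sd=1.0,
                            beta_age=0.3) -> pd.DataFrame:
    """Feature table drawn from the heteroscedastic mixed model itself."""
    r = np.random.default_rng(seed)
    df = covariate_frame(n, seed=seed + 1)
    sites = sorted(df["site"].unique())
    site_eff = dict(zip(sites, r.normal(0, site_sd, len(sites))))
    age_z = (df["age"] - df["age"].mean()) / df["age"].std(ddof=0)
    asd = (df["group"] == "ASD").astype(float)
    resid_sd = noise_sd * np.where(asd > 0.5, delta, 1.0)
    y = (beta_age * age_z + beta_group * asd
         + df["site"].map(site_eff) + r.normal(0, 1, n) * resid_sd)
    return make_feature_table(df, y.to_numpy())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
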