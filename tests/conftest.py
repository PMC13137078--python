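import numpy as np
import pandas as pd
import pytest

from tetherdyn import Schedule, compute_risk_table, default_design, simulate_study


def make_schedule(species, site, dates, weights, normalize=True, observed=None):
    """Build a Schedule from plain date strings and raw weights."""
    dates = np.array(dates, dtype="datetime64[D]")
    weights = np.asarray(weights, dtype=float)
    if normalize:
        weights = weights / weights.sum()
    if observed is None:
        observed = np.ones(len(dates), dtype=bool)
    return Schedule(
        species=species, site=site, dates=dates, weights=weights,
        observed=observed, normalized=normalize,
    )


def random_schedule(rng, label=("sp", "site"), n_min=3, n_max=16):
    """Random unit-mass schedule on a random strictly increasing date grid."""
    n = int(rng.integers(n_min, n_max + 1))
    start = np.datetime64("2022-04-01") + int(rng.integers(0, 30))
    gaps = rng.integers(1, 40, size=n - 1)
    dates = start + np.concatenate(([0], np.cumsum(gaps))).astype("timedelta64[D]")
    w = rng.random(n) ** 2
    w[int(rng.integers(0, n))] += 0.1  # guarantee positive mass
    return make_schedule(label[0], label[1], dates, w)


@pytest.fixture(scope="session")
def study():
    """One default six-site synthetic study and its risk table."""
    design = default_design(seed=11)
    tethers, habitat = simulate_study(design)
    return {
        "design": design,
        "tethers": tethers,
        "habitat": habitat,
        "risks": compute_risk_table(tethers),
    }


@pytest.fixture()
def tether_csv(tmp_path):
    def _write(rows, header="site,date,species,n_deployed,n_recovered,n_consumed"):
        path = tmp_path / "tethers.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    return _write
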