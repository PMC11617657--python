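import numpy as np
import pandas as pd
import pytest

from scentselect import synthetic


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by read-only tests."""
    return synthetic.simulate_study(seed=42, n_plants_per_subplot=2)


@pytest.fixture(scope="session")
def small_design():
    return synthetic.build_design(synthetic.DesignConfig(rng_seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_peak_row(sample_id, compound, area, rt=5.0, sample_type="floral", plant_id=None):
    return {
        "sample_id": sample_id,
        "plant_id": plant_id if plant_id is not None else (sample_id if sample_type == "floral" else ""),
        "date": "2019-07-01",
        "sample_type": sample_type,
        "compound": compound,
        "retention_time": rt,
        "peak_area": area,
    }


@pytest.fixture()
def toy_peak_table():
    """Six compounds engineered to fail/pass each filter rule.

    20 floral samples, 2 ambient samples.
      early_eluter: median RT 1.5 (fails retention_time)
      rare: detected in 1/20 floral samples (fails occurrence)
      airborne: floral mean / ambient mean = 3.9 (fails ambient_ratio)
      plasticizer: clean numbers but listed contaminant
      clean_a, clean_b: pass everything
    """
    rows = []
    floral_ids = [f"f{i}" for i in range(20)]
    for sid in floral_ids:
        rows.append(make_peak_row(sid, "early_eluter", 500.0, rt=1.5))
        rows.append(make_peak_row(sid, "clean_a", 800.0, rt=6.0))
        rows.append(make_peak_row(sid, "clean_b", 300.0, rt=9.0))
        rows.append(make_peak_row(sid, "plasticizer", 400.0, rt=12.0))
        rows.append(make_peak_row(sid, "airborne", 390.0, rt=7.0))
    rows.append(make_peak_row("f0", "rare", 900.0, rt=8.0))
    for sid in ("a0", "a1"):
        rows.append(make_peak_row(sid, "airborne", 100.0, rt=7.0, sample_type="ambient"))
        rows.append(make_peak_row(sid, "clean_a", 10.0, rt=6.0, sample_type="ambient"))
    return pd.DataFrame(rows)
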