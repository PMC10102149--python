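import numpy as np
import pandas as pd
import pytest

import twinmr as tm


@pytest.fixture(scope="session")
def toy_csv(tmp_path_factory):
    """3 families: 1 MZ pair, 1 DZ pair, 1 DZ twin pair + sibling (7 people)."""
    rows = [
        # fid, role, zyg, sex, age, ssi, ssp, dep, anx, rsb, ps_ssi, ps_ssp
        (1, "twin1", "MZ", 0, 24, 0, 1, 3, 2, 4, 0.1, -0.2),
        (1, "twin2", "MZ", 0, 24, 1, 2, 5, 4, 6, 0.2, -0.1),
        (2, "twin1", "DZ", 1, 30, 0, 1, 2, 1, 8, np.nan, np.nan),
        (2, "twin2", "DZ", 0, 30, 2, 3, 7, 6, 2, np.nan, np.nan),
        (3, "twin1", "DZ", 1, 22, 0, 2, 4, 3, 5, -0.5, 0.3),
        (3, "twin2", "DZ", 1, 22, 0, 1, 6, 5, 7, 0.6, 0.9),
        (3, "sibling", "", 0, 26, 1, 4, 8, 7, 3, np.nan, np.nan),
    ]
    df = pd.DataFrame(
        rows,
        columns=["family_id", "member_role", "zygosity", "sex", "age",
                 "ssi", "ssp", "dep", "anx", "rsb", "ps_ssi", "ps_ssp"],
    )
    path = tmp_path_factory.mktemp("data") / "toy.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def small_table():
    cfg = tm.SimulationConfig(
        n_mz_pairs=120, n_dz_pairs=200, n_sib_pairs=80, n_trios=20,
        genotyped_fraction=0.5, seed=42,
    )
    return tm.simulate_families(cfg)


@pytest.fixture(scope="session")
def forward_spec():
    return tm.MrdocSpec(instrument=tm.PS_SSA, exposure=tm.SSA, outcome=tm.PD)


@pytest.fixture(scope="session")
def quarter_scale_fit(forward_spec):
    """One MR-DoC fit on quarter-scale data, reused by several tests."""
    cfg = tm.SimulationConfig(seed=7, genotyped_fraction=0.4)
    tab = tm.simulate_families(cfg)
    model = tm.build_mrdoc(forward_spec, check_identification=False)
    ds = tm.assemble_analysis_dataset(tab, list(model.observed))
    fit = tm.fit_fiml(model, ds, tm.FitOptions(n_starts=1, seed=1))
    return cfg, model, ds, fit
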