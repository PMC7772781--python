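"""Shared fixtures: synthetic datasets at unit-test and study scale.

Session scope keeps the expensive simulations (study-scale genome, 100-seed
replication) to a single run each for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from enhancerscope.positional import factor_offset_summary, pair_nelfa_ctr9
from enhancerscope.synthetic_data import default_profile, simulate


@pytest.fixture(scope="session")
def minimal_profile():
    return default_profile("minimal")


@pytest.fixture(scope="session")
def minimal_ds(minimal_profile):
    """Tiny 2-chromosome dataset with coverage tracks."""
    return simulate(minimal_profile, 7)


@pytest.fixture(scope="session")
def paper_profile():
    return default_profile("paper2020")


@pytest.fixture(scope="session")
def paper_ds(paper_profile):
    """Study-scale dataset (peaks/genes/expression only; no tracks)."""
    return simulate(paper_profile, 42, with_tracks=False)


@pytest.fixture(scope="session")
def paper_ds_tracks(paper_profile):
    """Study-scale dataset including Ctr9 and Ser2p coverage tracks."""
    return simulate(paper_profile, 42, with_tracks=True, track_factors=("Ctr9", "Ser2p"))


@pytest.fixture(scope="session")
def hundred_seed_summaries(paper_profile):
    """Promoter offset means and per-class NELFA-Ctr9 distance means for
    100 independent simulations (seeds 0..99)."""
    rows = []
    for seed in range(100):
        ds = simulate(paper_profile, seed, with_tracks=False)
        means = {
            f: factor_offset_summary(ds.peaks[f], ds.genes, 2000, f).mean
            for f in ("NELFA", "Ser5p", "Ctr9")
        }
        se = [e for e in ds.enhancers if e.enh_class == "SE"]
        te = [e for e in ds.enhancers if e.enh_class == "TE"]
        d_se = [
            p.distance
            for p in pair_nelfa_ctr9(se, ds.peaks["NELFA"], ds.peaks["Ctr9"])
            if p.distance is not None
        ]
        d_te = [
            p.distance
            for p in pair_nelfa_ctr9(te, ds.peaks["NELFA"], ds.peaks["Ctr9"])
            if p.distance is not None
        ]
        rows.append(
            {
                "offsets": means,
                "pair_se_mean": float(np.mean(d_se)),
                "pair_te_mean": float(np.mean(d_te)),
            }
        )
    return rows
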