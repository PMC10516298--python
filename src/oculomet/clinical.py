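"""Composite clinical scores: BICAMS and (modified) MSFC.

BICAMS = mean of cohort-internal z-scores of SDMT, RAVLT and BVMT-R.
MSFC   = mean of z-scores of SDMT, -T25FW and 1/9HPT -- the sign flip
and reciprocal make "higher is better" hold for every component before
averaging.  z-scores use the sample-SD (n-1) convention against the
cohort itself; an external norm table (mean, sd per test) can be
supplied instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BICAMS_COMPONENTS = ("sdmt", "ravlt", "bvmtr")
MSFC_COMPONENTS = ("sdmt", "t25fw", "hpt9")
CLINICAL_OUTCOMES = ("edss", "sdmt", "bicams", "msfc")


class ZeroVarianceError(ValueError):
    """Raised when a composite component has no variance in the cohort."""


def _zscore(values: pd.Series, name: str,
            norms: dict | None = None) -> pd.Series:
    if norms is not None and name in norms:
        mean, sd = norms[name]
    else:
        mean = values.mean(skipna=True)
        sd = values.std(ddof=1, skipna=True)
    if not np.isfinite(sd) or sd == 0.0:
        raise ZeroVarianceError(f"component {name!r} has zero variance")
    return (values - mean) / sd


def compute_composites(cohort: pd.DataFrame,
                       norms: dict | None = None) -> pd.DataFrame:
    """Return a copy of the cohort table with bicams and msfc columns.

    Participants missing any component of a composite get a missing
    composite (no partial averaging).
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 participants to z-score")
    out = cohort.copy()
    z_sdmt = _zscore(out["sdmt"].astype(float), "sdmt", norms)
    z_ravlt = _zscore(out["ravlt"].astype(float), "ravlt", norms)
    z_bvmtr = _zscore(out["bvmtr"].astype(float), "bvmtr", norms)
    # walk time: slower is worse -> multiply by -1 before z-scoring
    z_t25fw = _zscore(-out["t25fw"].astype(float), "t25fw_neg", norms)
    # peg time: reciprocal so that higher means better dexterity
    z_hpt9 = _zscore(1.0 / out["hpt9"].astype(float), "hpt9_recip", norms)
    out["bicams"] = (z_sdmt + z_ravlt + z_bvmtr) / 3.0
    out["msfc"] = (z_sdmt + z_t25fw + z_hpt9) / 3.0
    return out
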