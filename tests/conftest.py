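import numpy as np
import pandas as pd
import pytest

from surveydetect import DetectionHistory


def make_history(rows, method="CT", habitat="forest", locations=None):
    """Build a DetectionHistory from a list of row lists (None = NA)."""
    rows = [[np.nan if v is None else float(v) for v in r] for r in rows]
    n = len(rows)
    locations = locations or [f"L{i + 1:02d}" for i in range(n)]
    index = pd.Index([f"{loc}-{habitat}-{method}" for loc in locations], name="site_id")
    matrix = pd.DataFrame(rows, index=index,
                          columns=[f"occ_{k + 1}" for k in range(len(rows[0]))])
    habs = [habitat] * n if isinstance(habitat, str) else list(habitat)
    covs = pd.DataFrame(
        {"method": method, "habitat": habs, "location_id": locations}, index=index
    )
    return DetectionHistory(matrix=matrix, covariates=covs)


@pytest.fixture
def sites_table():
    rows = []
    for li in range(1, 4):
        for hab in ("forest", "open"):
            for m in ("PT", "CT", "PAM"):
                rows.append(
                    {"site_id": f"L{li:02d}-{hab}-{m}", "location_id": f"L{li:02d}",
                     "habitat": hab, "method": m}
                )
    return pd.DataFrame(rows)
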