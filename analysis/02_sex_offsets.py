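#!/usr/bin/env python
"""Male-minus-female fracture T-score offsets and risk-equivalent cutpoints.

Pools the shipped study tables: the printed group summaries (Hong Kong
prospective fracture cases, the Australian series, community means) and
the synthetic European femoral-neck study set constructed to carry the
pooled aggregates of the published cross-sectional series.

Findings: men fracture at higher femoral-neck T-scores than women by
≈0.59 (European pooled series), 0.62 (Hong Kong prospective cases), while
the community (non-fracture) sex difference is 0.476 (US) / 0.51 (Hong
Kong) — the case offsets parallel, and slightly exceed, the community
offsets.  Shifting the female cutpoints by the case offsets gives the
risk-equivalent male cutpoints: −2.5 + 0.59 = −1.91 (≈−1.9, adopted −2.0)
and −2.7 + 0.62 = −2.08 (adopted −2.1).
"""

from importlib.resources import files
from pathlib import Path

import pandas as pd

from osteofrailia import (
    load_study_table,
    pooled_mean,
    risk_equivalent_cutpoint,
    sex_offset,
)

OUT = Path(__file__).resolve().parent.parent / "results"
DATA = files("osteofrailia") / "data"


def main() -> None:
    printed = load_study_table(str(DATA / "studies_printed.csv"))
    synthetic = load_study_table(str(DATA / "studies_fig1_synthetic.csv"))

    hk_cases = [r for r in printed if r.study_id == "mros_msos_hk_cases"]
    hk_comm = [r for r in printed if r.study_id == "hk_community"]
    us_comm = [r for r in printed if r.study_id == "nhanes3_community"]
    wong = [r for r in printed if r.study_id == "wong_aus_ffx"]

    rows = [
        ("EU pooled fracture series (synthetic study set)", sex_offset(synthetic, site="FN", region="EU")),
        ("HK prospective fracture cases", sex_offset(hk_cases)),
        ("Australian fracture series", sex_offset(wong)),
        ("HK community baseline", sex_offset(hk_comm)),
        ("US community (reference populations)", sex_offset(us_comm)),
    ]
    table = pd.DataFrame(rows, columns=["comparison", "offset_m_minus_f"])

    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "sex_offsets.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print()
    print("pooled EU fracture means:",
          f"F {pooled_mean(synthetic, sex_group='F'):.3f},",
          f"M {pooled_mean(synthetic, sex_group='M'):.3f},",
          f"mixed {pooled_mean(synthetic, sex_group='mixed'):.3f}")
    for f_cut, off in ((-2.5, 0.59), (-2.7, 0.62)):
        raw = risk_equivalent_cutpoint(f_cut, off)
        rounded = risk_equivalent_cutpoint(f_cut, off, 1)
        print(f"female {f_cut} + offset {off} -> male {raw:.2f} (rounded {rounded})")
    print(f"wrote {OUT / 'sex_offsets.csv'}")


if __name__ == "__main__":
    main()
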