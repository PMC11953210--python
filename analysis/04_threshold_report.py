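#!/usr/bin/env python
"""Composite threshold report: the osteofrailia proposal in one table.

Runs the default threshold-derivation config against the shipped registry:
per ethnicity, the female osteoporosis cutpoint and its Gaussian
prevalence, the male risk-equivalent cutpoint (raw and rounded), the
adopted male threshold and its prevalence, and the male/female prevalence
ratio; plus the configured single-site constants (total hip −1.7
standalone, lumbar spine −2.0 working).

Findings: adopted male thresholds −2.0 (US Caucasian, prevalence 22.7% vs
female 23.3%, ratio 0.97) and −2.1 (Hong Kong Chinese) give male low-BMD
categories prevalence-comparable to female osteoporosis.
"""

from pathlib import Path

from osteofrailia import (
    default_registry,
    default_threshold_config,
    derive_osteofrailia_report,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    report = derive_osteofrailia_report(default_threshold_config(), default_registry())
    frame = report.to_frame()
    for col in ("female_prevalence", "male_prevalence"):
        frame[col + "_pct"] = 100 * frame.pop(col)

    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "osteofrailia_report.csv", index=False)
    print(frame.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print()
    for s in report.site_thresholds:
        print(f"site {s.site}: T <= {s.cutpoint} [{s.status}] {s.note}")
    print(f"wrote {OUT / 'osteofrailia_report.csv'}")


if __name__ == "__main__":
    main()
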