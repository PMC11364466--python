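#!/usr/bin/env python
"""Assemble the Markdown report (bias-by-angle, measure scatter with r,
coefficient intervals, power curves) from the run directory."""

from camwm.pipeline import make_report

OUT = "results/run"


def main() -> None:
    out = make_report(OUT)
    print(f"report written to {out}")
    print(out.read_text()[:600])


if __name__ == "__main__":
    main()
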