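"""Final verdict assembly and report rendering.

The decision tree: a passing signal level short-circuits — agreement on the
raw signals implies agreement on everything derived from them, and the
lower levels are reported as implied-valid.  Otherwise the parameter and
event levels are both reported (parameter-level agreement can mask
compensating errors, so the event level is always assessed).  Every verdict
carries at least one machine-readable reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .event_level import EventStatus, EventVerdict
from .parameter_level import ParameterVerdict
from .signal_level import SignalVerdict


@dataclass
class Verdict:
    """Per-level outcome of the protocol."""

    signal: str                              # pass | fail | not_applicable
    parameter: dict[str, str]                # parameter -> valid|invalid(+biased)
    event: dict[str, str]                    # "<channel>:<task>" -> status
    notes: list[str] = field(default_factory=list)
    config_hash: str = ""

    def to_dict(self) -> dict:
        return {
            "signal": self.signal,
            "parameter": self.parameter,
            "event": self.event,
            "notes": self.notes,
            "config_hash": self.config_hash,
        }


def assemble_verdict(
    signal: SignalVerdict | None,
    parameters: dict[str, ParameterVerdict] | None,
    events: dict[str, EventVerdict] | None,
    config_hash: str = "",
) -> Verdict:
    """Combine the three levels into the protocol decision tree."""
    if signal is None and not parameters and not events:
        raise ValueError("no level was computed; nothing to decide")
    notes: list[str] = []
    if signal is None:
        sig = "not_applicable"
        notes.append(
            "signal level not computed (e.g. ECG vs PPG cannot be compared "
            "at the signal level)"
        )
    else:
        sig = "pass" if signal.passed else "fail"
        notes.extend(f"signal: {r}" for r in signal.reasons)
    param_map: dict[str, str] = {}
    event_map: dict[str, str] = {}
    if sig == "pass":
        notes.append(
            "signal-level agreement implies validity of derived parameters "
            "and events; lower levels reported as implied-valid"
        )
        for name, pv in (parameters or {}).items():
            param_map[name] = f"implied_valid ({pv.status} when computed)"
        for name, ev in (events or {}).items():
            event_map[name] = f"implied_valid ({ev.status.value} when computed)"
    else:
        for name, pv in (parameters or {}).items():
            status = pv.status + ("+biased" if pv.biased else "")
            param_map[name] = status
            notes.extend(f"parameter {name}: {r}" for r in pv.reasons)
        for name, ev in (events or {}).items():
            event_map[name] = ev.status.value
            notes.extend(f"event {name}: {r}" for r in ev.reasons)
    if not notes:
        notes.append("no decision rules triggered")
    return Verdict(
        signal=sig,
        parameter=param_map,
        event=event_map,
        notes=notes,
        config_hash=config_hash,
    )


def render_report(results, out_dir: str | Path, make_figures: bool = True) -> list[Path]:
    """Write the machine-readable report, tables and figures.

    ``results`` is a :class:`~wearvalid.protocol.ValidityResults`.  Output is
    deterministic for identical inputs and configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out / "verdict.json"
    p.write_text(json.dumps(results.verdict.to_dict(), indent=2, sort_keys=True))
    written.append(p)

    p = out / "summary.txt"
    p.write_text(results.summary())
    written.append(p)

    for name, df in results.tables().items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    if make_figures:
        from . import plots

        written += plots.render_all(results, out)
    return written
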