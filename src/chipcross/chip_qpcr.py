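"""ChIP-qPCR quantitation: percent-input from threshold cycles.

Enrichment of an immunoprecipitated target is expressed as

    percent input = 100 x 2^(CT_input - CT_IP)

optionally adjusting CT_input by ``input_dilution_log2`` cycles when only a
diluted input fraction was run (e.g. a 1% input needs log2(100) ≈ 6.64).
Fold enrichment normalises a treatment percent-input to a control's.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "QpcrMeasurement",
    "percent_input",
    "normalize_to_control",
    "percent_input_table",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One target's input and IP threshold cycles in one condition."""

    target_name: str
    ct_input: float
    ct_ip: float
    condition_label: str = ""

    def __post_init__(self) -> None:
        for label, ct in (("input", self.ct_input), ("IP", self.ct_ip)):
            if not math.isfinite(ct):
                raise ValueError(f"{self.target_name}: non-finite {label} CT")
            if not (0 <= ct <= 45):
                warnings.warn(
                    f"{self.target_name}: {label} CT {ct} outside the usual 0-45 range",
                    stacklevel=2,
                )


def percent_input(m: QpcrMeasurement, input_dilution_log2: float = 0.0) -> float:
    """Percent input: 100 x 2^((CT_input - dilution_adjust) - CT_IP)."""
    return 100.0 * 2.0 ** ((m.ct_input - input_dilution_log2) - m.ct_ip)


def normalize_to_control(treatment: float, control: float) -> float:
    """Fold enrichment of a treatment percent-input over a control's."""
    if control == 0:
        raise ValueError("control percent-input is zero; fold undefined")
    if control < 0 or treatment < 0:
        raise ValueError("percent-input values must be non-negative")
    return treatment / control


def percent_input_table(
    path: str, input_dilution_log2: float = 0.0, control_label: str | None = None
) -> pd.DataFrame:
    """Process a CT table TSV (target, condition, ct_input, ct_ip).

    Returns per-row percent input; when ``control_label`` is given, adds a
    ``fold_vs_control`` column normalising each target to that condition.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"target", "condition", "ct_input", "ct_ip"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.copy()
    df["percent_input"] = [
        percent_input(
            QpcrMeasurement(str(r.target), float(r.ct_input), float(r.ct_ip), str(r.condition)),
            input_dilution_log2,
        )
        for r in df.itertuples(index=False)
    ]
    if control_label is not None:
        control = (
            df[df["condition"] == control_label]
            .set_index("target")["percent_input"]
            .to_dict()
        )
        df["fold_vs_control"] = [
            normalize_to_control(p, control[t]) if t in control else float("nan")
            for t, p in zip(df["target"], df["percent_input"])
        ]
    return df
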