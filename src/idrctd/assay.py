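"""Condensate turbidity arithmetic.

Turbidity of a protein mixture at 550 nm is reported as the complement of
percent transmittance: a fully clear sample (100% transmittance) has 0%
turbidity, a strongly condensate-forming sample transmitting 5% has 95%
turbidity.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TurbidityReading", "turbidity_from_transmittance", "convert_table"]


@dataclass(frozen=True)
class TurbidityReading:
    transmittance_percent: float
    turbidity_percent: float


def turbidity_from_transmittance(transmittance_percent: float) -> TurbidityReading:
    """Complement rule: turbidity% = 100 - transmittance%."""
    t = float(transmittance_percent)
    if not 0.0 <= t <= 100.0:
        raise ValueError(f"transmittance must be in [0, 100], got {t}")
    return TurbidityReading(transmittance_percent=t, turbidity_percent=100.0 - t)


def convert_table(df, column: str = "transmittance"):
    """Add a ``turbidity`` column to a DataFrame of transmittance readings."""
    out = df.copy()
    out["turbidity"] = [
        turbidity_from_transmittance(v).turbidity_percent for v in out[column]
    ]
    return out
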