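"""Values that may be exact or right-censored lower bounds.

Censored cohort medians (no event in half the animals by end of follow-up)
and the growth delays derived from them are reported as ``">x"`` in study
tables.  :class:`BoundedValue` carries that distinction through arithmetic
and serialization so downstream reports can print the same notation.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BoundedValue:
    """A number of days that is either exact or a lower bound (``">x"``)."""

    value: float
    is_lower_bound: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"BoundedValue must be non-negative, got {self.value}")

    def __str__(self) -> str:
        prefix = ">" if self.is_lower_bound else ""
        return f"{prefix}{self.value:g}"

    def __float__(self) -> float:
        return float(self.value)

    @classmethod
    def parse(cls, text: str | float | int | "BoundedValue") -> "BoundedValue":
        """Parse ``"13.2"`` or ``">160.0"`` (canonical CSV serialization)."""
        if isinstance(text, BoundedValue):
            return text
        if isinstance(text, (int, float)):
            return cls(float(text))
        s = str(text).strip()
        if s.startswith(">"):
            return cls(float(s[1:]), is_lower_bound=True)
        return cls(float(s))


def as_float(x: "BoundedValue | float | int") -> float:
    """Numeric value for ranking; lower bounds rank at their bound."""
    return float(x)
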