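"""Clinical rating scale registry.

Three scales are modelled: the Hoehn & Yahr motor stage (ordinal 1-5 with
half stages), the UPDRS total score (0-199, higher = worse motor function),
and the MMSE (0-30, lower = worse cognition).  Each scale carries its valid
range, its quantization, and the template phrase used when a score is
rendered into (and parsed back out of) synthetic clinical note text.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Scale:
    name: str
    lo: float
    hi: float
    step: float | None  # quantization grid; None = continuous
    snap: str           # "floor" (stage reached only at boundary) or "round"
    template: str       # rendering template, one {value} slot

    def clamp(self, x: float) -> float:
        return min(self.hi, max(self.lo, x))

    def quantize(self, x: float) -> float:
        """Clamp to range and snap onto the scale grid.

        H&Y snaps down: a stage boundary counts only once truly crossed.
        Count-like scales (UPDRS, MMSE) round to the nearest point, which
        keeps quantization unbiased.
        """
        x = self.clamp(x)
        if self.step is None:
            return x
        import math

        q = x / self.step
        k = math.floor(round(q, 9)) if self.snap == "floor" else round(q)
        return self.clamp(k * self.step)

    def render(self, value: float) -> str:
        v = int(value) if float(value).is_integer() else value
        return self.template.format(value=v)


HY = Scale("hy", 1.0, 5.0, 0.5, "floor", "Hoehn and Yahr stage: {value}.")
UPDRS = Scale("updrs_total", 0.0, 199.0, 1.0, "round", "UPDRS total: {value}.")
MMSE = Scale("mmse", 0.0, 30.0, 1.0, "round", "MMSE: {value}/30.")

SCALES: dict[str, Scale] = {s.name: s for s in (HY, UPDRS, MMSE)}


def get_scale(name: str) -> Scale:
    try:
        return SCALES[name]
    except KeyError:
        raise KeyError(f"unknown scale {name!r}; known: {sorted(SCALES)}") from None
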