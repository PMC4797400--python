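"""MIRD organ mean absorbed doses from cumulated activities and S-factors.

The organ mean dose is the MIRD sum over source regions,

    D(rT) = sum_rS  Atilde(rS) * S(rT <- rS),

with Atilde in disintegrations per MBq administered and S in Gy per
disintegration, giving dose coefficients in Gy/MBq.  Absolute doses at an
administered activity A are coefficient x A.  Reporting follows the usual
preclinical convention: coefficients to two decimals, absolute doses to
two significant figures (raw doubles are retained internally).

A published coefficient table for the Lu-177-labeled anti-hK2 antibody in
LNCaP-xenografted mice is bundled (``reference_coefficients``) so dose
tables and therapy plans can be computed without re-running the fitting
and transport stages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from importlib import resources

from .transport import SFactorMatrix

__all__ = [
    "DoseReport",
    "organ_dose",
    "dose_table",
    "reference_coefficients",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class DoseReport:
    """Per-region dose coefficients and absolute doses at given activities.

    ``coefficients`` maps region -> (self Gy/MBq, total Gy/MBq);
    ``doses_at`` maps administered activity (MBq) -> region -> Gy (raw);
    rounded values are produced by :meth:`rounded_doses` /
    :meth:`to_frame`.
    """

    coefficients: dict[str, tuple[float, float]]
    doses_at: dict[float, dict[str, float]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region, (self_c, total_c) in self.coefficients.items():
            if self_c < 0 or total_c < 0:
                raise ValueError(f"{region}: negative dose coefficient")
            if self_c > total_c * (1 + 1e-9):
                raise ValueError(f"{region}: self-dose coefficient exceeds total")

    def rounded_doses(self, sig: int = 2) -> dict[float, dict[str, float]]:
        return {
            a: {r: round_sig(d, sig) for r, d in per_region.items()}
            for a, per_region in self.doses_at.items()
        }

    def to_frame(self, sig: int = 2) -> pd.DataFrame:
        """Table-style frame: one row per region, coefficient and dose columns."""
        activities = sorted(self.doses_at)
        rows = []
        for region, (self_c, total_c) in self.coefficients.items():
            row = {
                "region": region,
                "self_gy_per_mbq": round(self_c, 2),
                "total_gy_per_mbq": round(total_c, 2),
            }
            for a in activities:
                row[f"dose_gy_at_{a:g}_mbq"] = round_sig(self.doses_at[a][region], sig)
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        p = Path(path)
        self.to_frame().to_csv(p, index=False)
        meta = {
            "coefficients_raw": {r: list(c) for r, c in self.coefficients.items()},
            "doses_at_raw": {str(a): d for a, d in self.doses_at.items()},
            "provenance": self.provenance,
        }
        p.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def organ_dose(
    cumulated: dict[str, float], s: SFactorMatrix
) -> dict[str, tuple[float, float]]:
    """MIRD sum: region -> (self, total) dose coefficient in Gy/MBq.

    ``cumulated`` maps source region -> disintegrations per MBq
    administered.  Raises ``ValueError`` listing any source that has
    nonzero cumulated activity but no S-matrix entry.
    """
    matrix_sources = set(s.sources())
    missing = sorted(r for r, a in cumulated.items() if a != 0 and r not in matrix_sources)
    if missing:
        raise ValueError(
            "cumulated activity present but no S-factor entries for source "
            f"region(s): {missing}"
        )
    out: dict[str, tuple[float, float]] = {}
    for target in s.targets():
        total = sum(a * s.s.get((target, src), 0.0) for src, a in cumulated.items())
        self_d = cumulated.get(target, 0.0) * s.s.get((target, target), 0.0)
        out[target] = (self_d, total)
    return out


def dose_table(
    coefficients: dict[str, tuple[float, float]],
    activities: list[float],
    provenance: dict | None = None,
) -> DoseReport:
    """Absolute doses (Gy) = total coefficient x administered activity (MBq)."""
    for a in activities:
        if a < 0:
            raise ValueError(f"administered activity must be >= 0 MBq, got {a}")
    doses_at = {
        float(a): {r: c[1] * a for r, c in coefficients.items()} for a in activities
    }
    return DoseReport(
        coefficients=dict(coefficients),
        doses_at=doses_at,
        provenance=provenance or {},
    )


def reference_coefficients(kinetics: str = "lu177") -> dict[str, tuple[float, float]]:
    """Bundled published coefficients (Gy/MBq): region -> (self, total).

    ``kinetics`` selects the biokinetic dataset the published values were
    derived from: ``"lu177"`` (the Lu-177 antibody study itself) or
    ``"in111"`` (the In-111 surrogate study).
    """
    if kinetics not in ("lu177", "in111"):
        raise ValueError("kinetics must be 'lu177' or 'in111'")
    with resources.files("mobydose.data").joinpath(
        "reference_dose_coefficients.csv"
    ).open() as f:
        df = pd.read_csv(f, comment="#")
    return {
        str(r["region"]): (
            float(r[f"self_gy_per_mbq_{kinetics}"]),
            float(r[f"total_gy_per_mbq_{kinetics}"]),
        )
        for _, r in df.iterrows()
    }
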