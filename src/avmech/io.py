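"""Curve tables, parameter files and report writers.

Curve tables are UTF-8 comma-separated text with the header
``direction,rate_per_s,specimen,stretch,stress_mpa,stress_measure``.
One (direction, rate, specimen) group per curve; stretch strictly
increasing within a group.  Stress rows tagged ``engineering`` are
converted to Cauchy stress (``sigma = P * lambda``) on load, with the
conversion recorded in curve metadata.  Parameter files are flat
``key = value`` text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .energy import ElasticParams, ViscousParams
from .estimation import StressStrainCurve

__all__ = [
    "CurveTableError",
    "CURVE_COLUMNS",
    "read_curves",
    "write_curves",
    "read_params",
    "write_params",
]

CURVE_COLUMNS = [
    "direction",
    "rate_per_s",
    "specimen",
    "stretch",
    "stress_mpa",
    "stress_measure",
]
_MEASURES = {"cauchy", "engineering"}


class CurveTableError(ValueError):
    """Raised for malformed curve tables; names the offending line."""


def read_curves(path: str | Path) -> list[StressStrainCurve]:
    """Load a curve table, validating schema and per-curve invariants."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"specimen": str}, float_precision="round_trip")
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise CurveTableError(f"{path}: missing columns {missing}")

    # data row i of the frame sits on file line i + 2 (header is line 1)
    df["_line"] = df.index + 2

    bad = ~df["stress_measure"].isin(_MEASURES)
    if bad.any():
        line = int(df.loc[bad, "_line"].iloc[0])
        value = df.loc[bad, "stress_measure"].iloc[0]
        raise CurveTableError(
            f"{path}, line {line}: unknown stress_measure {value!r}"
        )

    curves: list[StressStrainCurve] = []
    for (direction, rate, specimen), group in df.groupby(
        ["direction", "rate_per_s", "specimen"], sort=True
    ):
        stretch = group["stretch"].to_numpy(float)
        stress = group["stress_mpa"].to_numpy(float)
        steps = np.diff(stretch)
        if np.any(steps <= 0.0):
            i = int(np.argmax(steps <= 0.0))
            line = int(group["_line"].iloc[i + 1])
            raise CurveTableError(
                f"{path}, line {line}: stretch not strictly increasing within "
                f"curve ({direction}, rate={rate}, specimen={specimen})"
            )
        metadata: dict = {}
        measures = set(group["stress_measure"])
        if "engineering" in measures:
            stress = stress * stretch
            metadata["converted_from"] = "engineering"
        try:
            curves.append(
                StressStrainCurve(
                    direction=str(direction),
                    rate=float(rate),
                    stretch=stretch,
                    stress=stress,
                    specimen=str(specimen),
                    metadata=metadata,
                )
            )
        except ValueError as exc:
            line = int(group["_line"].iloc[0])
            raise CurveTableError(f"{path}, line {line}: {exc}") from exc
    return curves


def write_curves(curves: list[StressStrainCurve], path: str | Path) -> None:
    """Write curves as a table; values keep full double precision."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "direction": c.direction,
                    "rate_per_s": c.rate,
                    "specimen": c.specimen,
                    "stretch": c.stretch,
                    "stress_mpa": c.stress,
                    "stress_measure": c.stress_measure,
                }
            )
        )
    # default float repr is shortest-round-trip; paired with the
    # round_trip parser in read_curves the table is bit-lossless
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


def write_params(params: dict[str, float | str], path: str | Path) -> None:
    """Write a flat key = value parameter file."""
    lines = []
    for key, value in params.items():
        if isinstance(value, float):
            lines.append(f"{key} = {value:.17g}")
        else:
            lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_params(path: str | Path) -> dict[str, float | str]:
    """Read a flat key = value file; numeric values are parsed as floats."""
    out: dict[str, float | str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise CurveTableError(f"{path}: malformed parameter line {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            out[key] = float(value)
        except ValueError:
            out[key] = value
    return out


def elastic_from_params(d: dict) -> ElasticParams:
    return ElasticParams(
        alpha=float(d["alpha"]), beta=float(d["beta"]),
        k1=float(d["k1"]), k2=float(d["k2"]),
    )


def viscous_from_params(d: dict) -> ViscousParams | None:
    if "eta1" not in d:
        return None
    return ViscousParams(
        eta1=float(d["eta1"]), eta2=float(d.get("eta2", 0.0)),
        rate=float(d.get("rate", "nan")),
    )
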