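"""Beta-galactosidase reporter arithmetic (Miller units).

Specific activity = [OD420 / (time_min x OD600)] x dilution_factor x 1000.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["BgalMeasurement", "miller_units", "read_measurements", "append_miller_column"]


@dataclass(frozen=True)
class BgalMeasurement:
    od420: float
    od600: float
    time_min: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.od600 <= 0:
            raise ValueError("od600 must be > 0")
        if self.time_min <= 0:
            raise ValueError("time_min must be > 0")
        if self.od420 < 0:
            raise ValueError("od420 must be >= 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


def miller_units(m: BgalMeasurement) -> float:
    return m.od420 / (m.time_min * m.od600) * m.dilution_factor * 1000.0


def read_measurements(path: str | Path) -> list[BgalMeasurement]:
    df = pd.read_csv(path, sep="\t")
    return [
        BgalMeasurement(
            od420=float(r.od420),
            od600=float(r.od600),
            time_min=float(r.time_min),
            dilution_factor=float(getattr(r, "dilution_factor", 1.0)),
        )
        for r in df.itertuples(index=False)
    ]


def append_miller_column(in_path: str | Path, out_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(in_path, sep="\t")
    if "dilution_factor" not in df.columns:
        df["dilution_factor"] = 1.0
    df["miller_units"] = [
        miller_units(
            BgalMeasurement(r.od420, r.od600, r.time_min, r.dilution_factor)
        )
        for r in df.itertuples(index=False)
    ]
    df.to_csv(out_path, sep="\t", index=False)
    return df
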