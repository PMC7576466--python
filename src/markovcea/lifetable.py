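"""Period life tables: age- and sex-indexed annual death probabilities.

A :class:`LifeTable` holds one row per (age, sex) with the annual probability
of death ``qx``.  Tables are read from and written to delimited text with the
header ``age,sex,qx`` (the dialect used for period life tables derived from
the Human Mortality Database).  On load the terminal age's ``qx`` is forced
to 1 so the table closes out, and ages must be contiguous within each sex.

Because real national life tables cannot be redistributed here, the package
ships a synthetic Gompertz–Makeham table calibrated to approximate Spanish
mortality around 2016 (see :func:`make_gompertz_table` for the parameters).
Any HMD-derived table in the same dialect can be dropped in instead.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

SEXES = ("M", "F")

#: Gompertz–Makeham parameters of the packaged synthetic table:
#: hazard mu(x) = a + b * exp(beta * x), annual qx = 1 - exp(-mu(x)).
#: Calibrated so that qx(65) and qx(84) sit close to Spanish period values
#: circa 2016 (women qx(65) ~ 0.006, qx(84) ~ 0.056; men ~ 0.011 / 0.087).
GOMPERTZ_SYNTHETIC_ES = {
    "F": {"a": 5.0e-4, "b": 2.3e-6, "beta": 0.120},
    "M": {"a": 2.0e-3, "b": 3.56e-6, "beta": 0.120},
}

_PACKAGED_TABLE = "gompertz_synthetic_es.csv"


class LifeTableError(ValueError):
    """Raised when a life table fails validation."""


@dataclass
class LifeTable:
    """Annual death probabilities ``qx`` indexed by integer age and sex.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``age`` (int), ``sex`` ({'M','F'}), ``qx`` (float in [0,1]).
        Ages must be contiguous per sex; the last age of each sex is forced
        to ``qx = 1`` during validation.
    """

    table: pd.DataFrame
    max_age: int = field(init=False)
    min_age: int = field(init=False)
    _qx: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = {"age", "sex", "qx"}
        if not required.issubset(df.columns):
            raise LifeTableError(
                f"life table must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        bad_sex = set(df["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise LifeTableError(f"unknown sex code(s) {sorted(bad_sex)}; expected M/F")
        if ((df["qx"] < 0) | (df["qx"] > 1)).any():
            rows = df.index[(df["qx"] < 0) | (df["qx"] > 1)].tolist()
            raise LifeTableError(f"qx outside [0, 1] at row(s) {rows}")
        self._qx = {}
        mins, maxs = [], []
        for sex in SEXES:
            sub = df[df["sex"] == sex].sort_values("age")
            if sub.empty:
                raise LifeTableError(f"life table has no rows for sex {sex!r}")
            ages = sub["age"].to_numpy()
            if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
                raise LifeTableError(f"ages not contiguous for sex {sex!r}")
            qx = sub["qx"].to_numpy(dtype=float).copy()
            qx[-1] = 1.0  # close out the table at the terminal age
            self._qx[sex] = (int(ages[0]), qx)
            mins.append(int(ages[0]))
            maxs.append(int(ages[-1]))
        self.min_age = max(mins)
        self.max_age = min(maxs)
        df.loc[df.groupby("sex")["age"].idxmax(), "qx"] = 1.0
        self.table = df.sort_values(["sex", "age"]).reset_index(drop=True)

    def qx(self, age: float, sex: str) -> float:
        """Annual death probability at ``age`` for ``sex``.

        Ages beyond the table clamp to the terminal row (qx = 1); ages below
        the first row clamp to the first row.
        """
        if sex not in SEXES:
            raise LifeTableError(f"unknown sex code {sex!r}; expected M/F")
        start, qx = self._qx[sex]
        idx = int(np.clip(int(age) - start, 0, len(qx) - 1))
        return float(qx[idx])

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        """Load a table from delimited text with header ``age,sex,qx``.

        Parse and validation errors name the offending line.
        """
        path = Path(path)
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise LifeTableError(f"could not parse {path}: {exc}") from exc
        required = {"age", "sex", "qx"}
        if not required.issubset(df.columns):
            raise LifeTableError(
                f"{path}: expected header with columns {sorted(required)}"
            )
        bad = df.index[(df["qx"] < 0) | (df["qx"] > 1)]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing
            lines = ", ".join(str(i + 2) for i in bad)
            raise LifeTableError(f"{path}: qx outside [0, 1] on line(s) {lines}")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def packaged_synthetic(cls) -> "LifeTable":
        """The packaged synthetic Gompertz–Makeham table (Spanish-like)."""
        text = resources.files("markovcea").joinpath("data", _PACKAGED_TABLE).read_text()
        return cls(pd.read_csv(io.StringIO(text)))


def make_gompertz_table(
    params: dict | None = None,
    age_min: int = 50,
    age_max: int = 110,
) -> LifeTable:
    """Build a synthetic Gompertz–Makeham life table.

    The hazard is ``mu(x) = a + b * exp(beta * x)`` per sex and the annual
    death probability ``qx = 1 - exp(-mu(x))``; the terminal age gets qx = 1.
    Defaults are the packaged Spanish-like calibration
    (:data:`GOMPERTZ_SYNTHETIC_ES`).
    """
    params = params or GOMPERTZ_SYNTHETIC_ES
    ages = np.arange(age_min, age_max + 1)
    frames = []
    for sex in SEXES:
        p = params[sex]
        mu = p["a"] + p["b"] * np.exp(p["beta"] * ages)
        qx = 1.0 - np.exp(-mu)
        frames.append(pd.DataFrame({"age": ages, "sex": sex, "qx": qx}))
    return LifeTable(pd.concat(frames, ignore_index=True))


def load_life_table(path: str | Path) -> LifeTable:
    """Alias for :meth:`LifeTable.from_csv` (pipeline entry point)."""
    return LifeTable.from_csv(path)
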