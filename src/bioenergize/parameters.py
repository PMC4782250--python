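"""Typed registry of bioenergetics model parameters.

Every symbol used by the consumption models (means, standard deviations,
units, provenance) lives in a :class:`ParameterRegistry`.  A packaged CSV
holds the default values for yellowtail kingfish (*Seriola lalandi*); user
overrides can be merged from a mapping or a YAML file.  Values are stored
exactly as given — unit conversions are centralised in
:mod:`bioenergize.bioenergetics`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "ParameterSpec",
    "ParameterRegistry",
    "MODEL_PARAMETERS",
    "FIXED_PARAMETERS",
    "MODELS",
    "load_registry",
    "write_registry",
]

VALID_SOURCES = frozenset({"derived", "measured", "literature", "assumed_10pct"})

#: Ordered parameter memberships per consumption model.  ``Speed`` is a
#: reference value only: the morphometric model derives swimming speed per
#: evaluation from Int, Lc, Ac, SL and AR rather than sampling it.
MODEL_PARAMETERS: dict[str, tuple[str, ...]] = {
    "accel": ("log_s", "b", "Act_day", "Act_night", "h_d", "h_n",
              "Oxy", "A", "Gv", "W", "Fj"),
    "morph": ("Int", "Lc", "Ac", "SL", "AR", "log_r", "z",
              "Oxy", "A", "Gv", "W", "Fj"),
    "physio": ("R_a", "R_b", "Q10", "T", "AM", "W", "Oxy", "A", "Gv", "Fj"),
}

MODELS = tuple(MODEL_PARAMETERS)

#: Symbols that are structural constants (held at their means in any
#: stochastic treatment): the diel hour budget and the activity multiplier.
FIXED_PARAMETERS = frozenset({"h_d", "h_n", "AM"})

_REQUIRED_COLUMNS = ("symbol", "mean", "sd", "units", "source")
_ASSUMED_SD_RTOL = 1e-9


@dataclass(frozen=True)
class ParameterSpec:
    """One named model parameter with its sampling distribution."""

    symbol: str
    mean: float
    sd: float
    units: str = ""
    source: str = "literature"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"parameter {self.symbol!r}: sd must be >= 0, got {self.sd}")
        if self.source not in VALID_SOURCES:
            raise ValueError(
                f"parameter {self.symbol!r}: unknown source {self.source!r} "
                f"(expected one of {sorted(VALID_SOURCES)})"
            )
        if self.source == "assumed_10pct":
            expected = 0.1 * abs(self.mean)
            if abs(self.sd - expected) > _ASSUMED_SD_RTOL * max(1.0, expected):
                raise ValueError(
                    f"parameter {self.symbol!r}: source 'assumed_10pct' requires "
                    f"sd == 0.1*|mean| = {expected!r}, got {self.sd!r}"
                )


@dataclass
class ParameterRegistry:
    """Mapping of symbol -> :class:`ParameterSpec` plus model memberships."""

    entries: dict[str, ParameterSpec]
    model_memberships: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(MODEL_PARAMETERS)
    )
    #: symbols present in the source table but not used by any model
    extra_symbols: list[str] = field(default_factory=list)

    def __getitem__(self, symbol: str) -> ParameterSpec:
        try:
            return self.entries[symbol]
        except KeyError:
            raise KeyError(f"no parameter {symbol!r} in registry") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries

    def mean(self, symbol: str) -> float:
        return self[symbol].mean

    def sd(self, symbol: str) -> float:
        return self[symbol].sd

    def means(self, symbols: Iterable[str]) -> dict[str, float]:
        return {s: self.mean(s) for s in symbols}

    def symbols_for(self, model: str) -> tuple[str, ...]:
        try:
            return self.model_memberships[model]
        except KeyError:
            raise KeyError(
                f"unknown model {model!r}; expected one of {sorted(self.model_memberships)}"
            ) from None

    def require_model(self, model: str) -> None:
        """Raise a configuration error naming any missing symbol for *model*."""
        missing = [s for s in self.symbols_for(model) if s not in self.entries]
        if missing:
            raise KeyError(
                f"model {model!r} requires parameter(s) {missing} missing from the registry"
            )

    def validate(self) -> None:
        for model in self.model_memberships:
            self.require_model(model)

    def updated(self, symbol: str, **changes) -> "ParameterRegistry":
        """Return a copy with *symbol* replaced (e.g. after a calibration fit)."""
        if symbol in self.entries:
            spec = replace(self.entries[symbol], **changes)
        else:
            spec = ParameterSpec(symbol=symbol, **changes)
        entries = dict(self.entries)
        entries[symbol] = spec
        return ParameterRegistry(entries, dict(self.model_memberships),
                                 list(self.extra_symbols))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"symbol": p.symbol, "mean": p.mean, "sd": p.sd, "units": p.units,
             "source": p.source, "notes": p.notes}
            for p in self.entries.values()
        ]
        return pd.DataFrame(rows, columns=["symbol", "mean", "sd", "units",
                                           "source", "notes"])


def _default_table_path():
    return importlib.resources.files("bioenergize") / "data" / "kingfish_parameters.csv"


def load_registry(path: str | Path | None = None,
                  overrides: Mapping | str | Path | None = None) -> ParameterRegistry:
    """Load a parameter registry from a CSV table.

    Parameters
    ----------
    path:
        CSV with columns ``symbol,mean,sd,units,source[,notes]``.  ``None``
        loads the packaged kingfish table.
    overrides:
        Optional mapping ``symbol -> {mean: ..., sd: ..., ...}`` or path to a
        YAML file with that structure, merged over the table.
    """
    if path is None:
        with importlib.resources.as_file(_default_table_path()) as p:
            table = pd.read_csv(p, keep_default_na=False, dtype={"symbol": str})
    else:
        table = pd.read_csv(path, keep_default_na=False, dtype={"symbol": str})

    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"parameter table is missing column(s) {missing_cols}")
    if "notes" not in table.columns:
        table["notes"] = ""

    dup = table["symbol"][table["symbol"].duplicated()].tolist()
    if dup:
        raise ValueError(f"parameter table defines symbol(s) {dup} more than once")

    entries: dict[str, ParameterSpec] = {}
    for row in table.itertuples(index=False):
        entries[row.symbol] = ParameterSpec(
            symbol=row.symbol, mean=float(row.mean), sd=float(row.sd),
            units=str(row.units), source=str(row.source), notes=str(row.notes),
        )

    if overrides is not None:
        if isinstance(overrides, (str, Path)):
            with open(overrides) as fh:
                overrides = yaml.safe_load(fh) or {}
        for symbol, changes in overrides.items():
            base = entries.get(symbol)
            if base is None:
                base = ParameterSpec(symbol=symbol, mean=0.0, sd=0.0)
            entries[symbol] = replace(base, **dict(changes))

    used = {s for syms in MODEL_PARAMETERS.values() for s in syms} | {"Speed"}
    extra = [s for s in entries if s not in used]

    registry = ParameterRegistry(entries, dict(MODEL_PARAMETERS), extra)
    registry.validate()
    return registry


def write_registry(registry: ParameterRegistry, path: str | Path) -> None:
    """Write a registry back to CSV; means and SDs round-trip bit-identically."""
    frame = registry.to_frame()
    # repr() of a float is its shortest exact decimal representation, so a
    # write/read cycle reproduces every value bit-for-bit.
    frame["mean"] = frame["mean"].map(repr)
    frame["sd"] = frame["sd"].map(repr)
    frame.to_csv(path, index=False)
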