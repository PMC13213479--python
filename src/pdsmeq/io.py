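"""CSV schema, configuration, subsetting, and parameter serialisation.

The single tabular interchange format is RFC-4180 CSV (UTF-8, "." decimal) with
header columns ``person_id, item_1..item_7, sex, race_ethnicity`` and an optional
``weight`` column (defaulting to 1 when absent).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contrasts import CodingError, normalize_race, normalize_sex
from .mnlfa import ActiveSet, ITEM_COLUMNS, MNLFAParameters

__all__ = [
    "SchemaError",
    "read_response_table",
    "write_response_table",
    "subset_filter",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
    "PipelineConfig",
]

log = logging.getLogger("pdsmeq")

REQUIRED_COLUMNS = ("person_id", *ITEM_COLUMNS, "sex", "race_ethnicity")


class SchemaError(ValueError):
    """Raised when an input table violates the expected CSV schema."""


def read_response_table(path, allow_continuous: bool = False) -> pd.DataFrame:
    """Read and validate a person-level item-response CSV.

    Items must be integers in 1..5 (unless ``allow_continuous``), sex and
    race/ethnicity must be on the supported whitelist; violations are reported
    with their row numbers.  A missing ``weight`` column defaults to 1.
    """
    path = Path(path)
    table = pd.read_csv(path)
    if table.empty:
        raise SchemaError(f"{path}: empty table")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    bad_rows: list[str] = []
    items = table[list(ITEM_COLUMNS)]
    if not allow_continuous:
        vals = items.to_numpy()
        ok = np.isin(vals, [1, 2, 3, 4, 5]) | ~np.isfinite(vals.astype(float))
        for r in np.unique(np.nonzero(~ok)[0]):
            bad_rows.append(f"row {r}: item value(s) outside 1..5")
    for col, norm in (("sex", normalize_sex), ("race_ethnicity", normalize_race)):
        for r, v in enumerate(table[col]):
            try:
                norm(v)
            except CodingError as err:
                bad_rows.append(f"row {r}: {err}")
    if bad_rows:
        preview = "; ".join(bad_rows[:10])
        raise SchemaError(f"{path}: {len(bad_rows)} invalid row(s): {preview}")
    if "weight" not in table.columns:
        log.info("%s: no weight column; defaulting all weights to 1", path)
        table["weight"] = 1.0
    elif (table["weight"] <= 0).any():
        raise SchemaError(f"{path}: weights must be positive")
    n_missing = int(items.isna().any(axis=1).sum())
    if n_missing:
        log.info("%s: %d person(s) with missing items (listwise-deleted downstream)", path, n_missing)
    return table


def write_response_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def subset_filter(table: pd.DataFrame, include_groups) -> pd.DataFrame:
    """Keep only rows from the named groups.

    ``include_groups`` may contain race labels ("Black"), sex labels ("female"),
    or intersectional labels ("Black female").  Used for sensitivity analyses
    (e.g. excluding White participants); downstream, the contrast design should
    be rebuilt with ``build_design(..., adapt_to_present=True)``.
    """
    include = list(include_groups)
    if not include:
        raise ValueError("include_groups must be non-empty")
    races, sexes, cells = set(), set(), set()
    for g in include:
        parts = str(g).strip().split()
        if len(parts) == 1:
            try:
                races.add(normalize_race(parts[0]))
                continue
            except CodingError:
                pass
            try:
                sexes.add(normalize_sex(parts[0]))
            except CodingError:
                raise CodingError(f"unrecognised group label {g!r}") from None
        elif len(parts) == 2:
            cells.add((normalize_race(parts[0]), normalize_sex(parts[1])))
        else:
            raise CodingError(f"unrecognised group label {g!r}")
    race_col = table["race_ethnicity"].map(normalize_race)
    sex_col = table["sex"].map(normalize_sex)
    mask = pd.Series(False, index=table.index)
    if races:
        mask |= race_col.isin(races)
    if sexes:
        mask |= sex_col.isin(sexes)
    if cells:
        mask |= pd.Series(list(zip(race_col, sex_col)), index=table.index).isin(cells)
    out = table[mask].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"no rows left after filtering to {include}")
    return out


# --- parameter (de)serialisation: round-trips exactly via repr of floats ----


def params_to_dict(params: MNLFAParameters) -> dict:
    return {
        "nu0": params.nu0.tolist(),
        "lambda0": params.lambda0.tolist(),
        "theta": params.theta.tolist(),
        "kappa": params.kappa.tolist(),
        "omega_mod": params.omega_mod.tolist(),
        "beta": params.beta.tolist(),
        "delta": params.delta.tolist(),
        "active": {
            "beta": params.active.beta.tolist(),
            "delta": params.active.delta.tolist(),
            "kappa": params.active.kappa.tolist(),
            "omega_mod": params.active.omega_mod.tolist(),
        },
    }


def params_from_dict(d: dict) -> MNLFAParameters:
    act = ActiveSet(
        beta=np.array(d["active"]["beta"], dtype=bool),
        delta=np.array(d["active"]["delta"], dtype=bool),
        kappa=np.array(d["active"]["kappa"], dtype=bool),
        omega_mod=np.array(d["active"]["omega_mod"], dtype=bool),
    )
    return MNLFAParameters(
        nu0=np.array(d["nu0"]),
        lambda0=np.array(d["lambda0"]),
        theta=np.array(d["theta"]),
        kappa=np.array(d["kappa"]),
        omega_mod=np.array(d["omega_mod"]),
        beta=np.array(d["beta"]),
        delta=np.array(d["delta"]),
        active=act,
    )


def save_params(params: MNLFAParameters, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(params_to_dict(params), indent=1))


def load_params(path) -> MNLFAParameters:
    return params_from_dict(json.loads(Path(path).read_text()))


@dataclass
class PipelineConfig:
    """Configuration of one full run (simulate -> CFA -> MNLFA selection -> scores)."""

    input_path: str | None = None  # CSV; if None, simulate `scenario` instead
    scenario: str = "final_model"
    n: int = 9360
    seed: int = 0
    continuous_items: bool = False
    weight_model: tuple | None = None
    impact_threshold: float = 0.10
    item_threshold: float = 0.05
    conditional_threshold: float = 0.05
    fdr_q: float = 0.05
    comparison_q: float = 0.05
    mgcfa_sqrt_g: bool = False
    run_mgcfa: bool = True
    output_dir: str = "results"

    def validate(self) -> None:
        for name in ("impact_threshold", "item_threshold", "conditional_threshold",
                     "fdr_q", "comparison_q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.input_path is None and self.n < 1:
            raise ValueError("n must be positive when simulating")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weight_model"] = list(self.weight_model) if self.weight_model else None
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if d.get("weight_model"):
            d["weight_model"] = tuple(d["weight_model"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
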