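"""File I/O and report serialization.

All concentrations in files are mol/L (mol/L of base pairs for lattice
DNA); unit conversions such as poly[d(I-C)] units -> bp happen only at
the CLI flag layer, so files carry a single unambiguous convention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult
from .linkage import LinkageResult, SaltSeries
from .model import AssayConditions, TitrationCurve

__all__ = [
    "POLY_DIC_BP_PER_UNIT", "round_half_away",
    "read_titration_csv", "write_titration_csv",
    "read_salt_series_csv", "write_salt_series_csv",
    "read_conditions", "write_report", "file_digest",
]

#: mol/L of base pairs contributed by 1.0 unit of poly[d(I-C)] in the assay
POLY_DIC_BP_PER_UNIT = 7.0e-3

_TITRATION_COLUMNS = ["o_total_M", "anisotropy", "sd", "n_rep"]
_SERIES_COLUMNS = ["na_M", "value", "sd", "series_label"]

_CONDITION_KEYS = {f.name for f in dataclasses.fields(AssayConditions)}


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (table convention: -8.25 -> -8.3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def file_digest(path) -> str:
    """Short sha256 of a file, for provenance logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def read_titration_csv(path, conditions: AssayConditions | None = None) -> TitrationCurve:
    """Read a titration table (columns o_total_M, anisotropy, sd, n_rep).

    Malformed cells and ordering violations are reported with the
    offending data row number (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in _TITRATION_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in _TITRATION_COLUMNS[:2]:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col!r} in data row {bad[0] + 1}")
    o = df["o_total_M"].astype(float).to_numpy()
    neg = np.nonzero(o < 0)[0]
    if neg.size:
        raise ValueError(f"{path}: negative concentration in data row {neg[0] + 1}")
    dec = np.nonzero(np.diff(o) <= 0)[0]
    if dec.size:
        raise ValueError(
            f"{path}: o_total_M not strictly increasing at data row {dec[0] + 2}")
    sd = df["sd"].astype(float).to_numpy() if "sd" in df.columns else None
    n_rep = df["n_rep"].astype(float).to_numpy() if "n_rep" in df.columns else None
    return TitrationCurve(conditions=conditions or AssayConditions(),
                          o_total=o, anisotropy=df["anisotropy"].astype(float).to_numpy(),
                          sd=sd, n_rep=n_rep)


def write_titration_csv(curve: TitrationCurve, path) -> None:
    pd.DataFrame({
        "o_total_M": curve.o_total,
        "anisotropy": curve.anisotropy,
        "sd": curve.sd,
        "n_rep": curve.n_rep.astype(int),
    }).to_csv(path, index=False, float_format="%.12g")


def read_salt_series_csv(path) -> dict[str, SaltSeries]:
    """Read salt series (columns na_M, value, sd, series_label) by label."""
    df = pd.read_csv(path)
    missing = [c for c in _SERIES_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "series_label" not in df.columns:
        df["series_label"] = "series"
    out = {}
    for label, grp in df.groupby("series_label", sort=False):
        grp = grp.sort_values("na_M")
        sd = grp["sd"].astype(float).to_numpy() if "sd" in grp.columns else None
        out[str(label)] = SaltSeries(label=str(label),
                                     na_conc=grp["na_M"].astype(float).to_numpy(),
                                     value=grp["value"].astype(float).to_numpy(),
                                     sd=sd)
    return out


def write_salt_series_csv(series_map: dict[str, SaltSeries], path) -> None:
    frames = [pd.DataFrame({"na_M": s.na_conc, "value": s.value, "sd": s.sd,
                            "series_label": label})
              for label, s in series_map.items()]
    pd.concat(frames).to_csv(path, index=False, float_format="%.12g")


def read_conditions(path) -> AssayConditions:
    """Load AssayConditions from a strict-schema YAML or JSON mapping."""
    text = Path(path).read_text()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text))
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of condition fields")
    unknown = set(data) - _CONDITION_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown condition keys {sorted(unknown)} "
                         f"(allowed: {sorted(_CONDITION_KEYS)})")
    return AssayConditions(**data)


def _result_payload(result) -> dict:
    if isinstance(result, FitResult):
        p = result.params
        return {
            "type": "fit",
            "params": {"kd": p.kd, "n_hill": p.n_hill, "phi": p.phi,
                       "r_unbound": p.r_unbound, "r_specific": p.r_specific},
            "stderr": dict(sorted(result.stderr.items())),
            "covariance": np.asarray(result.covariance).tolist(),
            "free": list(result.free_names),
            "fixed": sorted(result.fixed),
            "rss": result.rss,
            "converged": result.converged,
            "n_points": result.n_points,
            "display": {
                "log10_kd": round_half_away(np.log10(p.kd), 2),
                "kd_M": float(f"{p.kd:.3g}"),
                "phi_per_M": float(f"{p.phi:.3g}"),
            },
        }
    if isinstance(result, LinkageResult):
        return {
            "type": "linkage",
            "sk": result.sk, "sk_stderr": result.sk_stderr,
            "intercept": result.intercept,
            "dm_pe": result.dm_pe, "dm_other": result.dm_other,
            "psi": result.psi, "z": result.z,
            "display": {
                "sk": round_half_away(result.sk, 1),
                "dm_pe": round_half_away(result.dm_pe, 1),
                "dm_other": round_half_away(result.dm_other, 1),
            },
        }
    if isinstance(result, pd.DataFrame):
        return {"type": "table", "columns": list(result.columns),
                "rows": result.to_numpy().tolist(), "attrs": dict(result.attrs)}
    raise TypeError(f"cannot serialize result of type {type(result).__name__}")


def write_report(result, path, fmt: str = "json") -> None:
    """Serialize a fit/linkage result or scan table deterministically.

    JSON keeps full precision plus display-rounded copies following the
    summary-table conventions (log values to 2 decimals, ion counts to 1
    decimal, half away from zero).  CSV renders one row per parameter
    (fit), per scalar (linkage), or the table itself.
    """
    path = Path(path)
    payload = _result_payload(result)
    if fmt == "json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        if payload["type"] == "fit":
            rows = [{"parameter": k, "value": v,
                     "stderr": payload["stderr"].get(k, np.nan),
                     "fixed": k in payload["fixed"]}
                    for k, v in payload["params"].items()]
            pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
        elif payload["type"] == "linkage":
            rows = [{"quantity": k, "value": payload[k]}
                    for k in ("sk", "sk_stderr", "intercept", "dm_pe",
                              "dm_other", "psi", "z")]
            pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
        else:
            result.to_csv(path, index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown format {fmt!r}")
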