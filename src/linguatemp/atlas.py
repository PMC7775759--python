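"""Typological-atlas IO: reading WALS-style exports, binarization, filters.

Supports two delimited-text dialects: *wide* (one row per language, one
column per feature code) and *long* (one row per (language, feature,
value) triple plus per-language coordinate columns); the dialect is
auto-detected from the header.  Categorical value codes are turned into
binary present/absent samples by per-feature :class:`BinarizationRule`
mappings; a default rule set for 35 WALS features ships with the package
(our reconstruction — see data/binarization.yaml — editable by users).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geo import BootstrapSummary, FeatureSample

__all__ = [
    "AtlasTable", "BinarizationRule", "AtlasSchemaError",
    "read_atlas", "binarize_feature", "filter_samples",
    "write_results", "read_results",
    "load_binarization_rules", "load_reference_table",
]

log = logging.getLogger(__name__)

_MANDATORY = ["id", "name", "latitude", "longitude"]


class AtlasSchemaError(ValueError):
    """The input file does not have the expected columns."""


class UnmappedCodeError(ValueError):
    """A feature value code is not covered by the binarization rule."""


@dataclass
class AtlasTable:
    """Parsed atlas: language metadata plus a (language x feature) code table."""

    languages: pd.DataFrame   # index: language id; name, latitude, longitude, coord_ok
    codes: pd.DataFrame       # index: language id; columns: feature ids; str or NaN

    @property
    def feature_ids(self) -> list[str]:
        return list(self.codes.columns)

    def __len__(self) -> int:
        return len(self.languages)


@dataclass(frozen=True)
class BinarizationRule:
    """Mapping of one feature's categorical codes to {present, absent, excluded}."""

    feature_id: str
    label: str
    present: frozenset[str]
    absent: frozenset[str]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.present or not self.absent:
            raise ValueError(
                f"rule for {self.feature_id} must map at least one code to "
                "each of present and absent")
        overlap = (self.present & self.absent) | \
            (self.present & self.excluded) | (self.absent & self.excluded)
        if overlap:
            raise ValueError(
                f"rule for {self.feature_id} maps codes ambiguously: {overlap}")


def read_atlas(path: str | Path, delimiter: str | None = None) -> AtlasTable:
    """Read a wide or long delimited atlas export.

    Mandatory columns (case-insensitive): id, name, latitude, longitude.
    A long export additionally has ``feature`` and ``value`` columns.
    Rows with malformed coordinates are flagged (``coord_ok = False``),
    not dropped.
    """
    path = Path(path)
    import csv as _csv
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python",
                         dtype=str, comment="#")
    except (pd.errors.EmptyDataError, _csv.Error):
        raise AtlasSchemaError(f"{path}: empty or undelimited file") from None
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise AtlasSchemaError(f"{path}: missing mandatory columns {missing}")
    is_long = "feature" in df.columns and "value" in df.columns

    if is_long:
        lang = df.drop_duplicates("id").set_index("id")
        codes = df.pivot_table(index="id", columns="feature", values="value",
                               aggfunc="first")
        codes = codes.reindex(lang.index)
        codes.columns = [str(c) for c in codes.columns]
    else:
        lang = df.set_index("id")
        if lang.index.has_duplicates:
            dupes = lang.index[lang.index.duplicated()].unique().tolist()
            raise AtlasSchemaError(f"{path}: duplicate language ids {dupes}")
        feat_cols = [c for c in df.columns if c not in _MANDATORY
                     and c not in ("family", "area", "genus")]
        codes = lang[feat_cols].copy()
        codes.columns = [str(c).upper() for c in codes.columns]
    lat = pd.to_numeric(lang["latitude"], errors="coerce")
    lon = pd.to_numeric(lang["longitude"], errors="coerce")
    coord_ok = lat.between(-90, 90) & lon.between(-180, 180)
    languages = pd.DataFrame({
        "name": lang["name"], "latitude": lat, "longitude": lon,
        "coord_ok": coord_ok.fillna(False),
    })
    n_bad = int((~languages["coord_ok"]).sum())
    log.info("read %s: %d languages, %d features, %d flagged coordinates",
             path, len(languages), codes.shape[1], n_bad)
    return AtlasTable(languages=languages, codes=codes)


def binarize_feature(table: AtlasTable, rule: BinarizationRule) -> FeatureSample:
    """One feature's binary geolocated sample under a binarization rule.

    Languages with missing or explicitly excluded codes are dropped
    silently; languages with flagged coordinates are dropped with a log
    entry; an observed code the rule does not cover raises
    :class:`UnmappedCodeError` naming the code.
    """
    if rule.feature_id not in table.codes.columns:
        raise KeyError(f"feature {rule.feature_id} not in atlas")
    col = table.codes[rule.feature_id].dropna().astype(str).str.strip()
    observed = set(col.unique())
    unmapped = observed - rule.present - rule.absent - rule.excluded
    if unmapped:
        raise UnmappedCodeError(
            f"feature {rule.feature_id}: unmapped value code(s) "
            f"{sorted(unmapped)}")
    keep = col[~col.isin(rule.excluded)]
    if keep.empty:
        raise ValueError(f"feature {rule.feature_id}: no languages left "
                         "after binarization")
    meta = table.languages.loc[keep.index]
    bad = ~meta["coord_ok"]
    if bad.any():
        log.info("feature %s: dropping %d languages with flagged coordinates",
                 rule.feature_id, int(bad.sum()))
        keep = keep[~bad.to_numpy()]
        meta = meta[~bad.to_numpy()]
    return FeatureSample(
        feature_id=rule.feature_id,
        ids=keep.index.to_numpy(dtype=object),
        names=meta["name"].to_numpy(dtype=object),
        latitudes=meta["latitude"].to_numpy(dtype=float),
        longitudes=meta["longitude"].to_numpy(dtype=float),
        values=keep.isin(rule.present).to_numpy(dtype=np.int8),
    )


def filter_samples(samples: list[FeatureSample], min_size: int = 300,
                   exclude_ids: set[str] | None = None,
                   ) -> tuple[list[FeatureSample], list[dict]]:
    """Apply the language-exclusion list, then the minimum-sample filter.

    Excluded language ids (e.g. sign languages) are removed from every
    sample *before* the size check; samples with fewer than ``min_size``
    languages are then dropped.  Returns the retained samples and a log
    of every decision (no silent drops).
    """
    exclude_ids = set(exclude_ids or ())
    retained, decisions = [], []
    for s in samples:
        n_before = len(s)
        if exclude_ids:
            keep = ~np.isin(np.asarray(s.ids, dtype=str), list(exclude_ids))
            s = s.take(np.flatnonzero(keep))
        entry = {"feature_id": s.feature_id, "n_before_exclusion": n_before,
                 "n_after_exclusion": len(s),
                 "retained": len(s) >= min_size}
        decisions.append(entry)
        if entry["retained"]:
            retained.append(s)
        else:
            log.info("feature %s dropped: %d < %d languages",
                     s.feature_id, len(s), min_size)
    return retained, decisions


def write_results(summaries: list[BootstrapSummary], path: str | Path,
                  labels: dict[str, str] | None = None,
                  header_meta: dict | None = None) -> pd.DataFrame:
    """Write a ranked results table (descending temperature, 5 decimals).

    Ties in the median temperature are broken by feature id.  Optional
    ``header_meta`` key/values are written as ``# key=value`` comment
    lines (seed, version, ...).
    """
    if not summaries:
        raise ValueError("no summaries to write")
    labels = labels or {}
    rows = [{
        "feature": labels.get(s.feature_id, s.feature_id),
        "wals_id": s.feature_id,
        "n": s.n,
        "rho": s.rho_median,
        "sigma": s.sigma_median,
        "tau": s.tau_median,
        "tau_lo": s.tau_interval[0],
        "tau_hi": s.tau_interval[1],
        "n_infinite": s.n_infinite,
    } for s in summaries]
    df = pd.DataFrame(rows).sort_values(
        ["tau", "wals_id"], ascending=[False, True], kind="stable")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format="%.5f")
    return df.reset_index(drop=True)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results table written by :func:`write_results` (or the
    packaged reference table)."""
    return pd.read_csv(path, comment="#")


def load_reference_table() -> pd.DataFrame:
    """Published reference estimates for 35 WALS features.

    Columns: rank, feature, wals_id, rho (frequency), sigma (isogloss
    density), tau (temperature); per-feature bootstrap medians.
    """
    with resources.files("linguatemp.data").joinpath(
            "reference_temperatures.csv").open() as fh:
        return pd.read_csv(fh)


def load_binarization_rules(path: str | Path | None = None,
                            ) -> dict[str, BinarizationRule]:
    """Binarization rules from a YAML config (default: packaged rules)."""
    if path is None:
        with resources.files("linguatemp.data").joinpath(
                "binarization.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    rules = {}
    for fid, spec in raw["features"].items():
        rules[str(fid)] = BinarizationRule(
            feature_id=str(fid), label=spec.get("label", str(fid)),
            present=frozenset(map(str, spec["present"])),
            absent=frozenset(map(str, spec["absent"])),
            excluded=frozenset(map(str, spec.get("excluded", []))),
        )
    return rules
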