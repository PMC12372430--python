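"""Domain types and I/O for graded-response item banks and ordinal response data.

Response codes are 0-based internally (``0 .. K-1``); file readers accept a
declared origin and normalize on load.  Missing responses are represented as
``NaN`` in the float response array, never as an in-range sentinel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Item",
    "ItemBank",
    "ResponseMatrix",
    "RecodeSpec",
    "BankValidationError",
    "load_item_bank",
    "save_item_bank",
    "load_responses",
    "save_responses",
    "invert_categories",
    "recode_nrs_pain",
    "quantile_split",
]


class BankValidationError(ValueError):
    """Raised when an item bank or response matrix violates its invariants."""


@dataclass(frozen=True)
class Item:
    """One questionnaire item under the graded response model.

    Parameters
    ----------
    id : str
        Unique item label.
    instrument : str
        Originating instrument label (e.g. ``"PSQI"``, ``"ISI"``).
    n_categories : int
        Number of ordered response categories ``K >= 2``.
    discrimination : float
        Logit slope ``a > 0``; orientation fixed so higher theta means a
        better construct level.
    thresholds : tuple of float
        Strictly increasing category boundaries ``b_1 < ... < b_{K-1}``
        on the theta scale.
    reversed : bool
        Whether the item's raw categories were inverted to match the
        construct orientation.
    """

    id: str
    instrument: str
    n_categories: int
    discrimination: float
    thresholds: tuple[float, ...]
    reversed: bool = False

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise BankValidationError(
                f"item {self.id!r}: n_categories must be >= 2, got {self.n_categories}"
            )
        thr = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", thr)
        if len(thr) != self.n_categories - 1:
            raise BankValidationError(
                f"item {self.id!r}: expected {self.n_categories - 1} thresholds, "
                f"got {len(thr)}"
            )
        if any(not np.isfinite(t) for t in thr):
            raise BankValidationError(f"item {self.id!r}: non-finite threshold")
        if any(b >= c for b, c in zip(thr, thr[1:])):
            raise BankValidationError(
                f"item {self.id!r}: thresholds must be strictly increasing, got {thr}"
            )
        if not (self.discrimination > 0 and np.isfinite(self.discrimination)):
            raise BankValidationError(
                f"item {self.id!r}: discrimination must be finite and > 0, "
                f"got {self.discrimination}"
            )


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of unique :class:`Item` for one construct."""

    construct: str
    items: tuple[Item, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if not items:
            raise BankValidationError("item bank must be non-empty")
        ids = [it.id for it in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise BankValidationError(f"duplicate item ids: {dupes}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    def __getitem__(self, item_id: str) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, item_ids: Iterable[str]) -> "ItemBank":
        wanted = list(item_ids)
        missing = [i for i in wanted if i not in self.item_ids]
        if missing:
            raise KeyError(f"items not in bank: {missing}")
        return ItemBank(
            construct=self.construct,
            items=tuple(self[i] for i in wanted),
            provenance=self.provenance,
        )


@dataclass
class ResponseMatrix:
    """N x J ordinal responses with optional missing entries and covariates.

    ``responses`` is a float array where missing cells are ``NaN`` and
    observed cells are integer codes ``0 .. K_j - 1``.
    """

    respondent_ids: list[str]
    item_ids: list[str]
    responses: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        n, j = self.responses.shape
        if len(self.respondent_ids) != n:
            raise BankValidationError(
                f"{len(self.respondent_ids)} respondent ids for {n} rows"
            )
        if len(self.item_ids) != j:
            raise BankValidationError(f"{len(self.item_ids)} item ids for {j} columns")
        if len(self.covariates) not in (0, n):
            raise BankValidationError("covariate table length mismatch")
        obs = self.responses[~np.isnan(self.responses)]
        if obs.size and (np.any(obs < 0) or np.any(obs != np.round(obs))):
            raise BankValidationError("responses must be nonnegative integer codes or NaN")

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def column(self, item_id: str) -> np.ndarray:
        return self.responses[:, self.item_ids.index(item_id)]

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            respondent_ids=list(self.respondent_ids),
            item_ids=list(self.item_ids),
            responses=self.responses.copy(),
            covariates=self.covariates.copy(),
        )

    def validate_against(self, bank: ItemBank) -> None:
        """Check every observed code is below its item's category count."""
        for j, iid in enumerate(self.item_ids):
            if iid not in bank.item_ids:
                continue
            k = bank[iid].n_categories
            col = self.responses[:, j]
            bad = col[~np.isnan(col)] >= k
            if np.any(bad):
                raise BankValidationError(
                    f"item {iid!r}: response code >= K={k} present"
                )


@dataclass(frozen=True)
class RecodeSpec:
    """Declarative recoding rule for a raw variable."""

    rule: str  # "invert" | "nrs_pain_bands" | "quantile_split"
    parameters: dict = field(default_factory=dict)

    _RULES = ("invert", "nrs_pain_bands", "quantile_split")

    def __post_init__(self) -> None:
        if self.rule not in self._RULES:
            raise ValueError(f"unknown recode rule {self.rule!r}")
        if self.rule == "quantile_split":
            q = int(self.parameters.get("q", 0))
            if q < 2:
                raise ValueError("quantile_split requires q >= 2")


# ---------------------------------------------------------------------------
# bank serialization
# ---------------------------------------------------------------------------

def _bank_to_records(bank: ItemBank) -> list[dict]:
    return [
        {
            "id": it.id,
            "instrument": it.instrument,
            "n_categories": it.n_categories,
            "a": it.discrimination,
            "thresholds": list(it.thresholds),
            "reversed": it.reversed,
        }
        for it in bank.items
    ]


def save_item_bank(bank: ItemBank, path: str | Path, format: str | None = None) -> None:
    """Write a bank as JSON or CSV (format inferred from the suffix by default)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        payload = {
            "construct": bank.construct,
            "provenance": bank.provenance,
            "items": _bank_to_records(bank),
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    elif fmt == "csv":
        kmax = max(it.n_categories for it in bank.items)
        rows = []
        for it in bank.items:
            row: dict = {
                "id": it.id,
                "instrument": it.instrument,
                "n_categories": it.n_categories,
                "a": repr(it.discrimination),
                "reversed": int(it.reversed),
            }
            for k in range(1, kmax):
                row[f"b{k}"] = (
                    repr(it.thresholds[k - 1]) if k - 1 < len(it.thresholds) else ""
                )
            rows.append(row)
        df = pd.DataFrame(rows)
        df.attrs["construct"] = bank.construct
        with path.open("w") as fh:
            fh.write(f"# construct={bank.construct}\n")
            df.to_csv(fh, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_item_bank(path: str | Path, format: str | None = None) -> ItemBank:
    """Load and validate an item bank from JSON or CSV.

    Raises
    ------
    BankValidationError
        If thresholds are not strictly increasing or any field is invalid,
        naming the offending item.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise BankValidationError(f"malformed JSON in {path}: {exc}") from exc
        items = []
        for i, rec in enumerate(payload.get("items", [])):
            try:
                items.append(
                    Item(
                        id=str(rec["id"]),
                        instrument=str(rec.get("instrument", "")),
                        n_categories=int(rec["n_categories"]),
                        discrimination=float(rec["a"]),
                        thresholds=tuple(float(b) for b in rec["thresholds"]),
                        reversed=bool(rec.get("reversed", False)),
                    )
                )
            except KeyError as exc:
                raise BankValidationError(
                    f"item record {i}: missing field {exc}"
                ) from exc
        return ItemBank(
            construct=str(payload.get("construct", "")),
            items=tuple(items),
            provenance=str(payload.get("provenance", "")),
        )
    if fmt == "csv":
        construct = ""
        with path.open() as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first.lstrip("#").strip().split():
                    if tok.startswith("construct="):
                        construct = tok.split("=", 1)[1]
            else:
                fh.seek(0)
            # round_trip parsing keeps repr-written floats bit-exact
            df = pd.read_csv(fh, float_precision="round_trip")
        b_cols = sorted(
            (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        items = []
        for i, row in df.iterrows():
            k = int(row["n_categories"])
            thr = []
            for c in b_cols[: k - 1]:
                v = row[c]
                if pd.isna(v):
                    raise BankValidationError(
                        f"row {i} (item {row['id']!r}): missing threshold {c}"
                    )
                thr.append(float(v))
            items.append(
                Item(
                    id=str(row["id"]),
                    instrument=str(row.get("instrument", "")),
                    n_categories=k,
                    discrimination=float(row["a"]),
                    thresholds=tuple(thr),
                    reversed=bool(int(row.get("reversed", 0))),
                )
            )
        return ItemBank(construct=construct, items=tuple(items))
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# response matrix I/O
# ---------------------------------------------------------------------------

_RESERVED_COLS = ("respondent_id",)


def load_responses(
    path: str | Path,
    origin: int = 0,
    covariate_cols: Sequence[str] = ("gender",),
) -> ResponseMatrix:
    """Read a respondent-by-item CSV; empty cells are missing.

    ``origin`` declares the file's coding origin (0- or 1-based); codes are
    normalized to 0-based internally.
    """
    if origin not in (0, 1):
        raise ValueError("origin must be 0 or 1")
    df = pd.read_csv(path, dtype={"respondent_id": str})
    if "respondent_id" in df.columns:
        rids = df["respondent_id"].astype(str).tolist()
        df = df.drop(columns=["respondent_id"])
    else:
        rids = [str(i) for i in range(len(df))]
    cov_present = [c for c in covariate_cols if c in df.columns]
    covariates = df[cov_present].reset_index(drop=True)
    item_df = df.drop(columns=cov_present)
    responses = item_df.to_numpy(dtype=float) - origin
    if np.nanmin(responses, initial=0) < 0:
        raise BankValidationError("negative response code after origin shift")
    return ResponseMatrix(
        respondent_ids=rids,
        item_ids=list(item_df.columns),
        responses=responses,
        covariates=covariates,
    )


def save_responses(rm: ResponseMatrix, path: str | Path, origin: int = 0) -> None:
    df = pd.DataFrame(rm.responses + origin, columns=rm.item_ids)
    df.insert(0, "respondent_id", rm.respondent_ids)
    for c in rm.covariates.columns:
        df[c] = rm.covariates[c].to_numpy()
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# recoding rules
# ---------------------------------------------------------------------------

def invert_categories(
    rm: ResponseMatrix, item_id: str, bank: ItemBank | None = None, k: int | None = None
) -> ResponseMatrix:
    """Reverse an item's category codes: ``c -> K - 1 - c``; missing unchanged.

    ``K`` is taken from ``bank`` when given, else from ``k``, else from the
    observed maximum code.  Involution: applying twice restores the input.
    """
    if item_id not in rm.item_ids:
        raise KeyError(f"unknown item id {item_id!r}")
    if bank is not None:
        kk = bank[item_id].n_categories
    elif k is not None:
        kk = int(k)
    else:
        col = rm.column(item_id)
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(f"item {item_id!r} has no observed responses and no declared K")
        kk = int(obs.max()) + 1
    out = rm.copy()
    j = out.item_ids.index(item_id)
    col = out.responses[:, j]
    mask = ~np.isnan(col)
    col[mask] = (kk - 1) - col[mask]
    if np.any(col[mask] < 0):
        raise BankValidationError(f"item {item_id!r}: code >= K={kk} encountered")
    return out


_NRS_BAND_EDGES = (0, 3, 6)  # 0 | 1-3 | 4-6 | 7-10


def recode_nrs_pain(values) -> np.ndarray:
    """Map 0-10 numeric pain ratings to 4 ordinal bands.

    0 -> 0 (none), 1-3 -> 1 (mild), 4-6 -> 2 (moderate), 7-10 -> 3 (severe).
    """
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    vals = arr[mask]
    if vals.size and (np.any(vals < 0) or np.any(vals > 10)):
        raise ValueError("NRS pain values must be in 0..10")
    out = np.full(arr.shape, np.nan)
    codes = np.digitize(vals, [0.5, 3.5, 6.5])
    out[mask] = codes
    if np.isnan(arr).any():
        return out
    return out.astype(int)


def quantile_split(values, q: int) -> np.ndarray:
    """Assign ordinal codes ``0 .. q-1`` by empirical quantile bins.

    Bins are left-closed/right-open at the empirical quantiles with ties
    assigned to the lower bin; monotone in the input values.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    arr = np.asarray(values, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size == 0:
        raise ValueError("no observed values")
    if np.all(obs == obs[0]):
        raise ValueError("degenerate split: all values identical")
    # interior quantile cut points; ties go to the lower bin (right=True with
    # strictly-greater comparison below)
    cuts = np.quantile(obs, [i / q for i in range(1, q)], method="linear")
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    codes = np.zeros(mask.sum(), dtype=float)
    for c in cuts:
        codes += arr[mask] > c
    out[mask] = codes
    if np.isnan(arr).any():
        return out
    return out.astype(int)
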