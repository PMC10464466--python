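"""Item metadata, response tables, and cross-instrument harmonization.

Caregiver-report sensory items come from several instruments (Sensory
Profile versions SP1/SSP1/SP2/SSP2 and Sensory Experiences Questionnaire
versions SEQ-2.1/SEQ-3.0) with 5-point ordinal response scales. Two
instruments (SP1/SSP1) score frequency in the reverse direction, so their
responses are reflected (x -> K+1-x) to put all items on a common scale
where 5 means the behavior occurs more frequently. Homologous items —
analogous questions appearing on more than one instrument — are merged
into a single harmonized column; when a subject answered more than one
instrument's version of a homolog, a configurable instrument-precedence
order decides which response is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INSTRUMENTS",
    "PATTERNS",
    "DEFAULT_PRECEDENCE",
    "ItemDefinition",
    "ItemBank",
    "ResponseTable",
    "read_item_map",
    "harmonize",
    "SchemaError",
]

INSTRUMENTS = ("SP1", "SSP1", "SP2", "SSP2", "SEQ21", "SEQ30", "OTHER")
PATTERNS = ("HYPER", "HYPO", "SEEK")

#: Newest instrument version wins homolog conflicts by default.
DEFAULT_PRECEDENCE = ("SEQ30", "SEQ21", "SP2", "SSP2", "SP1", "SSP1", "OTHER")

#: Instruments whose raw responses are reverse-scored during harmonization.
REVERSED_INSTRUMENTS = frozenset({"SP1", "SSP1"})


class SchemaError(ValueError):
    """Input table violates the expected schema or an invariant."""


@dataclass(frozen=True)
class ItemDefinition:
    """Metadata for one raw (pre-harmonization) questionnaire item."""

    item_id: str
    instrument: str
    modality: str
    pattern: str
    reverse: bool
    homolog_group: str
    n_categories: int = 5

    def __post_init__(self):
        if self.instrument not in INSTRUMENTS:
            raise SchemaError(
                f"item {self.item_id}: unknown instrument {self.instrument!r}"
            )
        if self.pattern not in PATTERNS:
            raise SchemaError(f"item {self.item_id}: unknown pattern {self.pattern!r}")
        if self.n_categories < 2:
            raise SchemaError(f"item {self.item_id}: n_categories must be >= 2")
        if not self.homolog_group:
            raise SchemaError(f"item {self.item_id}: empty homolog_group")


class ItemBank:
    """A validated collection of :class:`ItemDefinition` with lookup helpers."""

    def __init__(self, items: Iterable[ItemDefinition]):
        items = list(items)
        ids = [it.item_id for it in items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate item_id(s): {sorted(dupes)}")
        self._items = {it.item_id: it for it in items}
        # homolog groups must agree on category count
        for g, members in self.homolog_groups().items():
            ks = {self._items[i].n_categories for i in members}
            if len(ks) > 1:
                raise SchemaError(f"homolog group {g!r} mixes category counts {sorted(ks)}")

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._items

    def __getitem__(self, item_id: str) -> ItemDefinition:
        return self._items[item_id]

    @property
    def item_ids(self) -> list:
        return list(self._items)

    def homolog_groups(self) -> dict:
        """Map homolog_group -> list of member item_ids."""
        groups: dict = {}
        for it in self._items.values():
            groups.setdefault(it.homolog_group, []).append(it.item_id)
        return groups

    def modalities(self, pattern: str | None = None) -> list:
        mods = []
        for it in self._items.values():
            if pattern is not None and it.pattern != pattern:
                continue
            if it.modality not in mods:
                mods.append(it.modality)
        return mods

    def subset(self, pattern: str | None = None, modality: str | None = None) -> "ItemBank":
        return ItemBank(
            it
            for it in self._items.values()
            if (pattern is None or it.pattern == pattern)
            and (modality is None or it.modality == modality)
        )

    def n_categories(self, group: str) -> int:
        members = self.homolog_groups()[group]
        return self._items[members[0]].n_categories


_ITEM_MAP_COLUMNS = (
    "item_id",
    "instrument",
    "modality",
    "pattern",
    "reverse",
    "homolog_group",
    "n_categories",
)


def read_item_map(path) -> ItemBank:
    """Read and validate an items.csv metadata table into an :class:`ItemBank`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_ITEM_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"item map missing column(s): {sorted(missing)}")
    bad_instr = df.loc[~df["instrument"].isin(INSTRUMENTS)]
    if not bad_instr.empty:
        raise SchemaError(
            "unknown instrument value(s) in rows "
            f"{bad_instr.index.tolist()}: {sorted(bad_instr['instrument'].unique())}"
        )
    bad_pat = df.loc[~df["pattern"].isin(PATTERNS)]
    if not bad_pat.empty:
        raise SchemaError(
            "unknown pattern value(s) in rows "
            f"{bad_pat.index.tolist()}: {sorted(bad_pat['pattern'].unique())}"
        )
    items = [
        ItemDefinition(
            item_id=row.item_id,
            instrument=row.instrument,
            modality=row.modality,
            pattern=row.pattern,
            reverse=str(row.reverse).strip().lower() in ("1", "true", "yes"),
            homolog_group=row.homolog_group,
            n_categories=int(row.n_categories),
        )
        for row in df.itertuples()
    ]
    return ItemBank(items)


@dataclass
class ResponseTable:
    """Wide table of harmonized ordinal responses.

    ``data`` is a DataFrame indexed by subject_id with one float column per
    harmonized item (values in 1..K, NaN = missing) plus the metadata held
    separately in ``study_id`` (a Series aligned to the index).
    """

    data: pd.DataFrame
    study_id: pd.Series
    n_categories: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.data.index.equals(self.study_id.index):
            raise SchemaError("data and study_id must share the same subject index")
        vals = self.data.to_numpy(float)
        for col in self.data.columns:
            k = self.n_categories.get(col, 5)
            v = self.data[col].dropna()
            if ((v < 1) | (v > k)).any():
                raise SchemaError(f"item {col!r}: responses outside 1..{k}")
        if self.data.shape[1] and np.all(np.isnan(vals), axis=1).any():
            empty = self.data.index[np.all(np.isnan(vals), axis=1)].tolist()
            raise SchemaError(f"subject(s) with no non-missing responses: {empty[:5]}")

    @property
    def items(self) -> list:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def subset_items(self, items: Sequence[str], drop_empty: bool = True) -> "ResponseTable":
        sub = self.data[list(items)]
        keep = ~sub.isna().all(axis=1) if drop_empty else slice(None)
        return ResponseTable(
            sub.loc[keep],
            self.study_id.loc[keep],
            {i: self.n_categories.get(i, 5) for i in items},
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "study_id", self.study_id)
        return out.reset_index(names="subject_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_categories=None) -> "ResponseTable":
        df = df.set_index("subject_id")
        study = df.pop("study_id")
        return cls(df.astype(float), study, n_categories or {})


def _reverse_map(x: np.ndarray, k: int) -> np.ndarray:
    return np.where(np.isnan(x), np.nan, k + 1 - x)


def harmonize(
    bank: ItemBank,
    raw: pd.DataFrame,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    missing_codes: Sequence = (),
) -> ResponseTable:
    """Harmonize long-format raw responses across instruments.

    Parameters
    ----------
    bank : ItemBank
        Metadata driving reverse-scoring and homolog merging.
    raw : DataFrame
        Long format with columns subject_id, study_id, item_id, response.
        A missing response may be NaN, blank, or one of ``missing_codes``.
    precedence : sequence of instrument labels
        When a subject answered several instruments' versions of the same
        homolog group, the response from the earliest instrument in this
        list is retained (default: newest instrument version first).

    Returns
    -------
    ResponseTable
        One column per homolog group, responses on the common 1..K scale
        (5 = more frequent behavior for the study instruments).
    """
    required = {"subject_id", "study_id", "item_id", "response"}
    missing = required - set(raw.columns)
    if missing:
        raise SchemaError(f"raw responses missing column(s): {sorted(missing)}")
    raw = raw.copy()
    raw["response"] = raw["response"].replace(list(missing_codes) + [""], np.nan)
    raw["response"] = pd.to_numeric(raw["response"], errors="raise").astype(float)
    raw = raw.dropna(subset=["response"])

    unknown = set(raw["item_id"]) - set(bank.item_ids)
    if unknown:
        raise SchemaError(f"responses reference unknown item(s): {sorted(unknown)[:5]}")

    rank = {instr: i for i, instr in enumerate(precedence)}
    meta = {i: bank[i] for i in set(raw["item_id"])}
    raw["group"] = raw["item_id"].map(lambda i: meta[i].homolog_group)
    raw["k"] = raw["item_id"].map(lambda i: meta[i].n_categories)
    raw["_rank"] = raw["item_id"].map(
        lambda i: rank.get(meta[i].instrument, len(precedence))
    )

    bad = raw.loc[(raw["response"] < 1) | (raw["response"] > raw["k"])]
    if not bad.empty:
        raise SchemaError(
            f"response(s) outside 1..K for item(s) {sorted(bad['item_id'].unique())[:5]}"
        )

    rev = raw["item_id"].map(lambda i: meta[i].reverse).to_numpy(bool)
    resp = raw["response"].to_numpy(float)
    raw["response"] = np.where(rev, raw["k"] - resp + 1, resp)

    # same-instrument duplicate responses within a homolog group are conflicts
    dup = raw.duplicated(subset=["subject_id", "group", "_rank"], keep=False)
    conflicting = raw.loc[dup].groupby(["subject_id", "group", "_rank"])["response"].nunique()
    if (conflicting > 1).any():
        where = conflicting[conflicting > 1].index.tolist()[:3]
        raise SchemaError(f"conflicting duplicate responses with equal precedence: {where}")

    raw = raw.sort_values("_rank", kind="stable").drop_duplicates(
        subset=["subject_id", "group"], keep="first"
    )
    wide = raw.pivot(index="subject_id", columns="group", values="response")
    study = raw.drop_duplicates("subject_id").set_index("subject_id")["study_id"]
    study = study.loc[wide.index]
    n_cat = {g: bank.n_categories(g) for g in wide.columns}
    return ResponseTable(wide, study, n_cat)
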