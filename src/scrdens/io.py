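"""Reading, writing and summarising trap layouts and capture histories.

File dialects
-------------
Trap file: one detector per line, ``detector_id x y [array_label]``.
Capture file: one detection per line,
``session animal_id occasion detector_id [key=value ...]``.
Both accept whitespace- or comma-delimited text (auto-detected) with an
optional header row; without a header the fixed column order above applies.
Coordinates are planar kilometres (pass ``units="m"`` to convert from metres);
the model is Euclidean and no geographic CRS handling is done here.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrapArray",
    "CaptureData",
    "SessionSummary",
    "read_traps",
    "write_traps",
    "read_captures",
    "write_captures",
    "filter_detections",
    "summarize_sessions",
    "convert_xlsx_captures",
]

SEX_CODES = ("F", "M", "U")


@dataclass
class TrapArray:
    """A fixed layout of detectors (hair snares) in planar km coordinates."""

    detector_ids: list[str]
    xy: np.ndarray  # (J, 2) float
    array_labels: Optional[np.ndarray] = None  # (J,) of str, e.g. "A".."E"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (J, 2) array of planar km coordinates")
        if len(self.detector_ids) != self.xy.shape[0]:
            raise ValueError("detector_ids and xy lengths differ")
        if self.n_detectors < 1:
            raise ValueError("a TrapArray needs at least one detector")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("trap coordinates must be finite")
        seen: set[str] = set()
        for did in self.detector_ids:
            if did in seen:
                raise ValueError(f"duplicate detector id {did!r}")
            seen.add(did)
        if self.array_labels is not None:
            self.array_labels = np.asarray(self.array_labels, dtype=object)
            if self.array_labels.shape[0] != self.n_detectors:
                raise ValueError("array_labels length mismatch")

    @property
    def n_detectors(self) -> int:
        return self.xy.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]

    def index_of(self, detector_id: str) -> int:
        try:
            return self.detector_ids.index(detector_id)
        except ValueError:
            raise KeyError(f"unknown detector id {detector_id!r}") from None


@dataclass
class CaptureData:
    """Binary individual x detector x occasion detection histories.

    ``y[i, j, k] == 1`` when animal *i* was detected at detector *j* on
    occasion *k*.  Detection is Bernoulli per animal-detector-occasion cell
    (binomial proximity model), so repeated samples of the same animal at
    the same snare within an occasion collapse to a single 1 in ``y``;
    the raw rows survive in ``records`` for sample-level summaries.
    """

    animal_ids: list[str]
    y: np.ndarray  # (n, J, K) in {0, 1}
    sex: Optional[np.ndarray] = None  # (n,) of {"F", "M", "U"}
    session_label: str = "session"
    records: Optional[pd.DataFrame] = None  # raw detections incl. attrs
    detector_ids: Optional[list[str]] = None  # column identities of y
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.uint8)
        if self.y.ndim != 3:
            raise ValueError("y must be (n_animals, n_detectors, n_occasions)")
        n = self.y.shape[0]
        if len(self.animal_ids) != n:
            raise ValueError("animal_ids length does not match y")
        if self.y.size and self.y.max() > 1:
            raise ValueError("y entries must be 0 or 1")
        if self.n_occasions < 1:
            raise ValueError("need at least one occasion")
        if n and not np.all(self.y.reshape(n, -1).any(axis=1)):
            bad = [self.animal_ids[i] for i in np.nonzero(~self.y.reshape(n, -1).any(axis=1))[0]]
            raise ValueError(f"animals with zero detections: {bad}")
        if self.sex is None:
            self.sex = np.full(n, "U", dtype=object)
        else:
            self.sex = np.asarray(self.sex, dtype=object)
            if self.sex.shape[0] != n:
                raise ValueError("sex length does not match number of animals")
            bad_codes = set(self.sex) - set(SEX_CODES)
            if bad_codes:
                raise ValueError(f"sex codes must be F/M/U, got {sorted(bad_codes)}")

    @property
    def n_animals(self) -> int:
        return self.y.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.y.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[2]

    @property
    def n_detections(self) -> int:
        """Number of nonzero animal-detector-occasion cells."""
        return int(self.y.sum())


@dataclass
class SessionSummary:
    """Per-occasion survey statistics with totals, means and SDs.

    ``u`` counts individuals detected for the first time on each occasion,
    ``n`` individuals detected, ``detections`` nonzero detection cells and
    ``detectors_visited`` detectors with at least one detection.  When raw
    records are available a ``samples`` column counts raw rows (e.g. hair
    samples), which may exceed ``detections``.
    """

    table: pd.DataFrame  # one row per occasion
    totals: pd.Series
    means: pd.Series
    sds: pd.Series
    n_animals: int
    session_label: str = "session"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"Session {self.session_label}: {self.n_animals} individuals",
                 self.table.to_string(index=False)]
        lines.append("totals: " + ", ".join(f"{k}={v:g}" for k, v in self.totals.items()))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# parsing helpers

def _sniff_table(path: str | Path, expected_first_cols: Sequence[str]) -> pd.DataFrame:
    """Read a whitespace- or comma-delimited table with optional header."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty file")
    sep = "," if "," in lines[0] else r"\s+"
    first = [t.strip() for t in (lines[0].split(",") if sep == "," else lines[0].split())]
    has_header = first[0].lower() == expected_first_cols[0]
    df = pd.read_csv(
        _io.StringIO("\n".join(lines)),
        sep=sep,
        header=0 if has_header else None,
        dtype=str,
        engine="python",
    )
    if not has_header:
        ncol = df.shape[1]
        names = list(expected_first_cols[:ncol])
        names += [f"extra{i}" for i in range(ncol - len(names))]
        df.columns = names
    else:
        df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_traps(path: str | Path, units: str = "km") -> TrapArray:
    """Read a trap layout file into a :class:`TrapArray`.

    Rows keep file order.  Duplicate detector ids and non-numeric
    coordinates raise ``ValueError`` naming the offending id / line.
    """
    df = _sniff_table(path, ("detector_id", "x", "y", "array_label"))
    if not {"detector_id", "x", "y"} <= set(df.columns):
        raise ValueError(f"{path}: need columns detector_id, x, y")
    xy = np.empty((len(df), 2))
    for i, (xs, ys) in enumerate(zip(df["x"], df["y"])):
        try:
            xy[i, 0] = float(xs)
            xy[i, 1] = float(ys)
        except (TypeError, ValueError):
            raise ValueError(f"{path}: non-numeric coordinate on data line {i + 1}") from None
    if units == "m":
        xy /= 1000.0
    elif units != "km":
        raise ValueError("units must be 'km' or 'm'")
    labels = df["array_label"].to_numpy() if "array_label" in df.columns else None
    return TrapArray(list(df["detector_id"]), xy, labels)


def write_traps(traps: TrapArray, path: str | Path) -> None:
    with open(path, "w") as fh:
        cols = "detector_id x y" + (" array_label" if traps.array_labels is not None else "")
        fh.write(cols + "\n")
        for j, did in enumerate(traps.detector_ids):
            line = f"{did} {traps.xy[j, 0]:.9f} {traps.xy[j, 1]:.9f}"
            if traps.array_labels is not None:
                line += f" {traps.array_labels[j]}"
            fh.write(line + "\n")


def read_captures(
    path: str | Path,
    traps: TrapArray,
    n_occasions: Optional[int] = None,
) -> CaptureData:
    """Read a capture file against a trap layout.

    Each row is one detection: ``session animal_id occasion detector_id``
    plus optional ``key=value`` attributes (a ``sex=F|M`` attribute is
    promoted to a per-animal covariate).  Repeated identical rows collapse
    to a single 1 in the binary tensor.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty capture file")
    rows = []
    start = 0
    first = lines[0].replace(",", " ").split()
    if first and first[0].lower() == "session":
        start = 1
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        toks = ln.replace(",", " ").split()
        if len(toks) < 4:
            raise ValueError(f"{path}: line {lineno}: expected at least 4 columns")
        session, animal, occ_s, det = toks[:4]
        try:
            occ = int(occ_s)
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: non-integer occasion {occ_s!r}") from None
        attrs = {}
        for tok in toks[4:]:
            if "=" not in tok:
                raise ValueError(f"{path}: line {lineno}: attribute {tok!r} is not key=value")
            k, v = tok.split("=", 1)
            attrs[k] = v
        if det not in traps.detector_ids:
            raise ValueError(f"{path}: line {lineno}: unknown detector {det!r}")
        rows.append({"session": session, "animal_id": animal, "occasion": occ,
                     "detector_id": det, **attrs})
    rec = pd.DataFrame(rows)
    max_occ = int(rec["occasion"].max())
    if n_occasions is None:
        n_occasions = max_occ
    if (rec["occasion"] < 1).any() or max_occ > n_occasions:
        bad = rec.loc[(rec["occasion"] < 1) | (rec["occasion"] > n_occasions), "occasion"].iloc[0]
        raise ValueError(f"{path}: occasion {bad} outside 1..{n_occasions}")
    return captures_from_records(rec, traps, n_occasions)


def captures_from_records(
    records: pd.DataFrame,
    traps: TrapArray,
    n_occasions: int,
    session_label: Optional[str] = None,
) -> CaptureData:
    """Build a :class:`CaptureData` from a raw detection-record table."""
    animals = list(dict.fromkeys(records["animal_id"]))  # keep first-seen order
    a_index = {a: i for i, a in enumerate(animals)}
    d_index = {d: j for j, d in enumerate(traps.detector_ids)}
    y = np.zeros((len(animals), traps.n_detectors, n_occasions), dtype=np.uint8)
    for _, r in records.iterrows():
        y[a_index[r["animal_id"]], d_index[r["detector_id"]], int(r["occasion"]) - 1] = 1
    sex = np.full(len(animals), "U", dtype=object)
    if "sex" in records.columns:
        for a, grp in records.groupby("animal_id"):
            vals = set(grp["sex"].dropna()) - {""}
            vals.discard("U")
            if len(vals) > 1:
                raise ValueError(f"conflicting sex codes for animal {a!r}: {sorted(vals)}")
            if vals:
                sex[a_index[a]] = vals.pop()
    label = session_label or str(records["session"].iloc[0])
    return CaptureData(animals, y, sex, session_label=label,
                       records=records.reset_index(drop=True),
                       detector_ids=list(traps.detector_ids))


def write_captures(data: CaptureData, traps: TrapArray, path: str | Path) -> None:
    """Write a capture file (one row per raw record, or per tensor cell)."""
    with open(path, "w") as fh:
        if data.records is not None:
            attr_cols = [c for c in data.records.columns
                         if c not in ("session", "animal_id", "occasion", "detector_id")]
            fh.write("session animal_id occasion detector_id" + "\n")
            for _, r in data.records.iterrows():
                extras = " ".join(
                    f"{c}={r[c]}" for c in attr_cols if pd.notna(r[c]) and r[c] != ""
                )
                fh.write(f"{r['session']} {r['animal_id']} {int(r['occasion'])} "
                         f"{r['detector_id']}" + (f" {extras}" if extras else "") + "\n")
        else:
            fh.write("session animal_id occasion detector_id sex\n")
            idx = np.argwhere(data.y == 1)
            for i, j, k in idx:
                fh.write(f"{data.session_label} {data.animal_ids[i]} {k + 1} "
                         f"{traps.detector_ids[j]} sex={data.sex[i]}\n")


# ---------------------------------------------------------------------------
# filtering and summaries

class _StrictAttrs(dict):
    """Attribute mapping that names available keys when one is missing."""

    def __missing__(self, key):
        raise KeyError(
            f"detection attribute {key!r} not present (available: {sorted(self)})"
        )


def filter_detections(
    data: CaptureData,
    predicate: Callable[[dict], bool],
    traps: Optional[TrapArray] = None,
) -> CaptureData:
    """Keep only detections whose attributes satisfy ``predicate``.

    Animals left without any detection are dropped.  The returned data's
    ``meta`` reports ``n_detections_removed`` (raw records removed) and
    ``n_animals_dropped``.  A predicate touching an attribute key absent
    from the records raises ``KeyError``.
    """
    if data.records is None:
        raise ValueError("filter_detections needs raw records (read_captures provides them)")
    rec = data.records
    core = ("session", "animal_id", "occasion", "detector_id")
    attr_cols = [c for c in rec.columns if c not in core]
    keep = np.zeros(len(rec), dtype=bool)
    for i, (_, row) in enumerate(rec.iterrows()):
        attrs = _StrictAttrs({c: row[c] for c in attr_cols if pd.notna(row[c])})
        keep[i] = bool(predicate(attrs))
    kept = rec[keep]
    n_removed = int((~keep).sum())
    if kept.empty:
        raise ValueError("predicate removed every detection")
    out = captures_from_records(kept, _traps_like(data, traps), data.n_occasions,
                                session_label=data.session_label)
    out.meta["n_detections_removed"] = n_removed
    out.meta["n_animals_dropped"] = data.n_animals - out.n_animals
    # carry over sexes known from the unfiltered data
    known = {a: s for a, s in zip(data.animal_ids, data.sex)}
    out.sex = np.array([known.get(a, "U") for a in out.animal_ids], dtype=object)
    return out


def _traps_like(data: CaptureData, traps: Optional[TrapArray]) -> TrapArray:
    if traps is not None:
        return traps
    if data.detector_ids is None:
        raise ValueError("pass a TrapArray: this CaptureData carries no detector ids")
    return TrapArray(list(data.detector_ids),
                     np.zeros((len(data.detector_ids), 2)))


def summarize_sessions(data: CaptureData) -> SessionSummary:
    """Per-occasion survey statistics (new individuals, detections, ...).

    ``detections`` counts nonzero tensor cells per occasion; when raw
    records exist a ``samples`` column additionally counts raw rows.
    """
    n, J, K = data.y.shape
    first_occ = np.full(n, K, dtype=int)
    for i in range(n):
        occs = np.nonzero(data.y[i].any(axis=0))[0]
        if occs.size:
            first_occ[i] = occs[0]
    u = np.bincount(first_occ, minlength=K + 1)[:K]
    n_k = data.y.any(axis=1).sum(axis=0)
    detections = data.y.sum(axis=(0, 1))
    visited = data.y.any(axis=0).sum(axis=0)
    table = pd.DataFrame({
        "occasion": np.arange(1, K + 1),
        "u": u,
        "n": n_k.astype(int),
        "detections": detections.astype(int),
        "detectors_visited": visited.astype(int),
    })
    if data.records is not None:
        samples = data.records.groupby("occasion").size()
        table["samples"] = table["occasion"].map(samples).fillna(0).astype(int)
    metrics = [c for c in table.columns if c != "occasion"]
    return SessionSummary(
        table=table,
        totals=table[metrics].sum(),
        means=table[metrics].mean(),
        sds=table[metrics].std(ddof=1),
        n_animals=n,
        session_label=data.session_label,
    )


def convert_xlsx_captures(
    xlsx_path: str | Path,
    out_path: str | Path,
    sheet: int | str = 0,
    column_map: Optional[dict] = None,
) -> pd.DataFrame:
    """Thin converter from an XLSX encounter-history sheet to the text dialect.

    ``column_map`` maps the sheet's column names onto
    ``session/animal_id/occasion/detector_id`` (plus optional attribute
    columns).  Note that published encounter-history workbooks typically
    omit trap coordinates, so a matching trap file must be supplied (or
    generated) separately.
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    if column_map:
        df = df.rename(columns=column_map)
    need = {"session", "animal_id", "occasion", "detector_id"}
    if not need <= set(df.columns):
        raise ValueError(f"XLSX sheet must provide columns {sorted(need)} after mapping")
    extra = [c for c in df.columns if c not in need]
    with open(out_path, "w") as fh:
        fh.write("session animal_id occasion detector_id\n")
        for _, r in df.iterrows():
            extras = " ".join(f"{c}={r[c]}" for c in extra if pd.notna(r[c]))
            fh.write(f"{r['session']} {r['animal_id']} {int(r['occasion'])} "
                     f"{r['detector_id']}" + (f" {extras}" if extras else "") + "\n")
    return df
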