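"""Data model for infinite-sites haplotype samples.

A sample is ``D = [X, nu]``: a binary matrix ``X`` whose distinct rows are
haplotypes (columns are segregating sites, 1 = derived character) and a
vector ``nu`` of positive multiplicities.  The same shape describes every
*ancestral configuration* on the backward path from the sample to its most
recent common ancestor (MRCA); removing a mutation simply deletes the
corresponding column, so the MRCA is an empty matrix with count vector
``[1]``.

Three backward-in-time operations connect configurations:

* **coalescence** of two copies of a haplotype with multiplicity >= 2
  (decrements ``nu_i``);
* **type-I mutation removal**: erase the private mutation of a singleton
  row when the row stays unique (deletes the column);
* **type-II mutation removal**: erase the private mutation of a singleton
  row when the row becomes identical to another row (deletes the row and
  the column, incrementing the merge row's multiplicity).

The module also provides the small XML/TSV file dialects, validation, the
consensus-root recode used when the ancestral state is unknown, and a
canonical key for configurations equal up to row and column permutation
(used for memoisation by the exact recursion).
"""

from __future__ import annotations

import enum
import io
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataFormatError, DataValidationError, StuckConfigurationError

__all__ = [
    "EventKind",
    "EvolutionEvent",
    "K69Dataset",
    "AncestralConfig",
    "ValidationReport",
    "read_dataset",
    "parse_dataset",
    "write_dataset",
    "validate",
    "consensus_root_recode",
    "enumerate_events",
    "apply_event",
    "target_coefficient",
    "canonical_key",
]


class EventKind(enum.Enum):
    COALESCENCE = "coalescence"
    MUT_TYPE_I = "mutation_type_I"
    MUT_TYPE_II = "mutation_type_II"


@dataclass(frozen=True)
class EvolutionEvent:
    """One backward step on an ancestral configuration.

    ``row`` indexes the haplotype the event acts on; ``column`` is the
    deleted site for mutation removals (``None`` for coalescence);
    ``merge_row`` is the index of the merge haplotype for type-II removals.
    Indices are 0-based.
    """

    kind: EventKind
    row: int
    column: int | None = None
    merge_row: int | None = None


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[tuple[str, str], ...] = ()

    def raise_if_invalid(self) -> None:
        if not self.ok:
            msgs = "; ".join(f"{rule} at {loc}" for rule, loc in self.violations)
            raise DataValidationError(f"invalid dataset: {msgs}")


def _as_matrix(haplotypes) -> np.ndarray:
    X = np.asarray(haplotypes)
    if X.size == 0:
        # normalise all empty shapes to (r, 0)
        r = X.shape[0] if X.ndim == 2 else 1
        return np.zeros((r, 0), dtype=np.uint8)
    return np.ascontiguousarray(X, dtype=np.uint8)


@dataclass
class _Configuration:
    """Shared array container for samples and ancestral configurations."""

    X: np.ndarray
    nu: np.ndarray
    site_labels: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        self.X = _as_matrix(self.X)
        self.nu = np.asarray(self.nu, dtype=np.int64)
        if self.nu.ndim != 1 or self.nu.shape[0] != self.X.shape[0]:
            raise DataValidationError(
                f"multiplicity vector of length {self.nu.shape} does not match "
                f"{self.X.shape[0]} haplotype rows"
            )
        if not self.site_labels:
            self.site_labels = tuple(str(j + 1) for j in range(self.X.shape[1]))
        elif len(self.site_labels) != self.X.shape[1]:
            raise DataValidationError("site_labels length does not match column count")

    @property
    def n(self) -> int:
        """Total number of sampled sequences, n = sum(nu)."""
        return int(self.nu.sum())

    @property
    def num_haplotypes(self) -> int:
        return self.X.shape[0]

    @property
    def num_sites(self) -> int:
        return self.X.shape[1]

    def haplotype_string(self, i: int) -> str:
        return "".join(str(int(v)) for v in self.X[i])

    def copy(self):
        return replace(self, X=self.X.copy(), nu=self.nu.copy())


@dataclass
class K69Dataset(_Configuration):
    """An observed infinite-sites sample ``D = [X, nu]``."""

    def initial_config(self) -> "AncestralConfig":
        return AncestralConfig(
            X=self.X.copy(), nu=self.nu.copy(),
            site_labels=self.site_labels, name=self.name,
        )


@dataclass
class AncestralConfig(_Configuration):
    """A configuration on the backward path from sample to MRCA."""

    @property
    def is_mrca(self) -> bool:
        return self.num_sites == 0 and self.num_haplotypes == 1 and int(self.nu[0]) == 1

    @classmethod
    def mrca(cls) -> "AncestralConfig":
        return cls(X=np.zeros((1, 0), dtype=np.uint8), nu=np.array([1]))


# ---------------------------------------------------------------------------
# validation


def validate(d: _Configuration, *, allow_fixed_columns: bool = False) -> ValidationReport:
    """Check every model invariant of ``d`` and report violations.

    ``allow_fixed_columns`` relaxes the all-one-column ban (such columns
    arise legitimately inside ancestral configurations mid-path, but a
    sample file containing one is not segregating against the known
    all-zero root).
    """
    v: list[tuple[str, str]] = []
    X, nu = d.X, d.nu
    bad = np.argwhere((X != 0) & (X != 1))
    for i, j in bad[:5]:
        v.append(("non-binary entry", f"row {i + 1}, column {j + 1}"))
    seen: dict[bytes, int] = {}
    for i in range(X.shape[0]):
        key = X[i].tobytes()
        if key in seen:
            v.append(("rows not distinct", f"rows {seen[key] + 1} and {i + 1}"))
        else:
            seen[key] = i
    for i in np.nonzero(nu < 1)[0]:
        v.append(("multiplicity < 1", f"row {i + 1}"))
    if d.num_haplotypes == 0 or d.n < 1:
        v.append(("empty sample", "dataset"))
    if X.shape[0] > 0:
        col_ones = X.sum(axis=0)
        for j in np.nonzero(col_ones == 0)[0]:
            v.append(("column all-zero (site not segregating)", f"column {j + 1}"))
        if not allow_fixed_columns:
            # weighted: a column carried by every sampled sequence
            carriers = (X.astype(np.int64).T @ np.maximum(nu, 0))
            for j in np.nonzero((carriers >= d.n) & (col_ones == X.shape[0]))[0]:
                v.append(("column all-one (site not segregating)", f"column {j + 1}"))
    return ValidationReport(ok=not v, violations=tuple(v))


# ---------------------------------------------------------------------------
# file I/O  (XML dialect: <k69data name="..."><haplotype count="2">1000</haplotype>...)


def _parse_haplotype_rows(rows: list[tuple[str, str]], name: str) -> K69Dataset:
    mats, counts = [], []
    width = None
    for lineno, (bits, count) in enumerate(rows, start=1):
        if not set(bits) <= {"0", "1"}:
            raise DataFormatError(
                f"haplotype {lineno}: characters restricted to 0/1, got {bits!r}"
            )
        if width is None:
            width = len(bits)
        elif len(bits) != width:
            raise DataFormatError(
                f"haplotype {lineno}: length {len(bits)} != {width} of first row"
            )
        try:
            c = int(count)
        except ValueError:
            c = -1
        if c < 1:
            raise DataFormatError(f"haplotype {lineno}: count must be a positive integer")
        mats.append([int(ch) for ch in bits])
        counts.append(c)
    if not mats:
        raise DataFormatError("no haplotypes in file")
    X = np.array(mats, dtype=np.uint8).reshape(len(mats), width or 0)
    d = K69Dataset(X=X, nu=np.array(counts), name=name)
    validate(d).raise_if_invalid()
    return d


def parse_dataset(text: str, format: str, name: str = "") -> K69Dataset:
    """Parse a dataset from a string in the ``xml`` or ``tsv`` dialect."""
    if format == "xml":
        try:
            root = ET.fromstring(text)
        except ET.ParseError as exc:
            raise DataFormatError(f"XML parse failure: {exc}") from exc
        if root.tag != "k69data":
            raise DataFormatError(f"expected root element <k69data>, got <{root.tag}>")
        rows = [
            (hap.text or "", hap.get("count", ""))
            for hap in root.findall("haplotype")
        ]
        return _parse_haplotype_rows(rows, name=root.get("name", name))
    if format == "tsv":
        rows = []
        for lineno, line in enumerate(io.StringIO(text), start=1):
            line = line.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataFormatError(f"line {lineno}: expected BINARYSTRING<TAB>COUNT")
            rows.append((parts[0], parts[1]))
        return _parse_haplotype_rows(rows, name=name)
    raise ValueError(f"unknown format {format!r} (expected 'xml' or 'tsv')")


def read_dataset(path, format: str | None = None) -> K69Dataset:
    """Read a validated :class:`K69Dataset` from an XML or TSV file.

    When ``format`` is omitted it is inferred from the file extension.
    """
    path = os.fspath(path)
    if format is None:
        format = "tsv" if path.endswith((".tsv", ".txt")) else "xml"
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    name = os.path.splitext(os.path.basename(path))[0]
    return parse_dataset(text, format=format, name=name)


def write_dataset(d: K69Dataset, path, format: str | None = None) -> None:
    path = os.fspath(path)
    if format is None:
        format = "tsv" if path.endswith((".tsv", ".txt")) else "xml"
    lines: list[str] = []
    if format == "xml":
        lines.append(f'<k69data name="{d.name}">')
        for i in range(d.num_haplotypes):
            lines.append(
                f'  <haplotype count="{int(d.nu[i])}">{d.haplotype_string(i)}</haplotype>'
            )
        lines.append("</k69data>")
    elif format == "tsv":
        lines.append(f"# {d.name}" if d.name else "#")
        for i in range(d.num_haplotypes):
            lines.append(f"{d.haplotype_string(i)}\t{int(d.nu[i])}")
    else:
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# consensus root recode


def consensus_root_recode(d: K69Dataset) -> K69Dataset:
    """Recode each column so the weighted majority character becomes 0.

    Used when the root state is unknown: the accepted expedient substitutes
    the consensus sequence for the root.  Columns left all-zero after
    recoding are dropped.  The input is not modified.
    """
    X = d.X.copy()
    n = d.n
    carriers = X.astype(np.int64).T @ d.nu
    flip = carriers * 2 > n
    X[:, flip] ^= 1
    keep = X.sum(axis=0) > 0
    labels = tuple(l for l, k in zip(d.site_labels, keep) if k)
    return K69Dataset(X=X[:, keep], nu=d.nu.copy(), site_labels=labels,
                      name=d.name + " (consensus-rooted)" if d.name else "")


# ---------------------------------------------------------------------------
# event enumeration / application (object layer over the fast kernels)


def _enumerate_fast(X: np.ndarray, nu: np.ndarray):
    """Enumerate backward events on raw arrays.

    Returns a list of ``(kind, row, col, merge_row)`` tuples with ``kind``
    an :class:`EventKind`, in deterministic order: coalescences by row,
    then type-I removals by row, then type-II removals by row.
    """
    coal = [(EventKind.COALESCENCE, int(i), None, None)
            for i in np.nonzero(nu >= 2)[0]]
    type1: list[tuple] = []
    type2: list[tuple] = []
    r, s = X.shape
    if s:
        col_rows = X.sum(axis=0)            # rows carrying each column
        private = np.nonzero(col_rows == 1)[0]
        if private.size:
            owner = X[:, private].argmax(axis=0)
            by_row: dict[int, list[int]] = {}
            for j, i in zip(private, owner):
                if nu[i] == 1:
                    by_row.setdefault(int(i), []).append(int(j))
            row_index = {X[k].tobytes(): k for k in range(r)} if by_row else {}
            for i in sorted(by_row):
                t1_cols, t2 = [], []
                tmp = X[i].copy()
                for j in by_row[i]:
                    # zero the lone 1 and look for a now-identical row
                    tmp[j] = 0
                    match = row_index.get(tmp.tobytes())
                    tmp[j] = 1
                    if match is not None and match != i:
                        t2.append((j, int(match)))
                    else:
                        t1_cols.append(j)
                if t1_cols:
                    type1.append((EventKind.MUT_TYPE_I, i, min(t1_cols), None))
                if len(t2) > 1:
                    raise DataValidationError(
                        f"internal consistency: row {i + 1} has multiple "
                        "type-II-eligible columns, impossible under infinite sites"
                    )
                if t2:
                    j, m = t2[0]
                    type2.append((EventKind.MUT_TYPE_II, i, j, m))
    return coal + type1 + type2


def _apply_fast(X, nu, kind, row, col, merge):
    if kind is EventKind.COALESCENCE:
        nu2 = nu.copy()
        nu2[row] -= 1
        return X, nu2, None
    if kind is EventKind.MUT_TYPE_I:
        keep = np.ones(X.shape[1], dtype=bool)
        keep[col] = False
        return np.ascontiguousarray(X[:, keep]), nu, keep
    # type II: drop row and column, add the count to the merge row
    keep_c = np.ones(X.shape[1], dtype=bool)
    keep_c[col] = False
    keep_r = np.ones(X.shape[0], dtype=bool)
    keep_r[row] = False
    nu2 = nu.copy()
    nu2[merge] += 1
    return np.ascontiguousarray(X[np.ix_(keep_r, keep_c)]), nu2[keep_r], keep_c


def enumerate_events(c: AncestralConfig) -> list[EvolutionEvent]:
    """All backward events applicable to ``c``.

    Raises :class:`StuckConfigurationError` when a non-MRCA configuration
    has no event (the data is then not reachable from an all-zero root).
    """
    if c.is_mrca:
        return []
    events = [EvolutionEvent(kind=k, row=i, column=j, merge_row=m)
              for k, i, j, m in _enumerate_fast(c.X, c.nu)]
    if not events:
        raise StuckConfigurationError(
            "non-MRCA configuration admits no backward event; "
            "data is not a perfect phylogeny rooted at the all-zero sequence"
        )
    return events


def apply_event(c: AncestralConfig, e: EvolutionEvent) -> AncestralConfig:
    """Apply one backward event, returning a new configuration."""
    _check_applicable(c, e)
    X, nu, keep_c = _apply_fast(c.X, c.nu, e.kind, e.row, e.column, e.merge_row)
    if keep_c is None:
        labels = c.site_labels
    else:
        labels = tuple(l for l, k in zip(c.site_labels, keep_c) if k)
    return AncestralConfig(X=X.copy(), nu=nu.copy(), site_labels=labels, name=c.name)


def _check_applicable(c: AncestralConfig, e: EvolutionEvent) -> None:
    ok = any(
        e.kind is k and e.row == i and e.column == j and e.merge_row == m
        for k, i, j, m in _enumerate_fast(c.X, c.nu)
    )
    if not ok:
        raise DataValidationError(f"event {e} is not applicable to this configuration")


def target_coefficient(c: AncestralConfig, e: EvolutionEvent, theta: float) -> float:
    """Numerator coefficient of the recursion term for event ``e``.

    The one-step target transition probability is
    ``coefficient / (n (n - 1 + theta))`` with ``n`` taken from ``c``.
    Coalescence of row i contributes ``nu_i (nu_i - 1)``, a type-I removal
    ``theta``, and a type-II removal into merge row b ``theta (nu_b + 1)``.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    if e.kind is EventKind.COALESCENCE:
        v = int(c.nu[e.row])
        return float(v * (v - 1))
    if e.kind is EventKind.MUT_TYPE_I:
        return float(theta)
    return float(theta) * (int(c.nu[e.merge_row]) + 1)


# ---------------------------------------------------------------------------
# canonical key


def canonical_key(c: _Configuration):
    """Hashable key invariant under simultaneous row and column permutation.

    Reachable configurations of infinite-sites data are rooted perfect
    phylogenies, so the column supports form a laminar family over rows.
    The key is the canonical code of the corresponding mutation tree: each
    node carries the number of identical columns with that support and the
    multiplicity of the (at most one) haplotype whose mutation set ends
    there, with child codes sorted.  Two configurations get equal keys iff
    they are equal up to a row permutation (with matched multiplicities)
    and a column permutation.

    For the rare non-laminar matrix (only ever fed in directly by a user,
    never reached from valid data) a brute-force minimisation over row
    permutations is used up to 9 rows.
    """
    X, nu = c.X, c.nu
    r, s = X.shape
    # group identical columns; supports as frozensets of row indices
    supports: dict[bytes, int] = {}
    sup_sets: list[np.ndarray] = []
    for j in range(s):
        b = X[:, j].tobytes()
        if b in supports:
            supports[b] += 1
        else:
            supports[b] = 1
            sup_sets.append(X[:, j].astype(bool))
    mults = [supports[col.astype(np.uint8).tobytes()] for col in sup_sets]

    # laminarity check + containment forest
    order = sorted(range(len(sup_sets)),
                   key=lambda k: -int(sup_sets[k].sum()))
    parent = [-1] * len(sup_sets)  # -1 = root
    for a_pos, a in enumerate(order):
        for b in order[:a_pos][::-1]:  # smallest candidate container first
            inter = sup_sets[a] & sup_sets[b]
            if not inter.any():
                continue
            if (inter == sup_sets[a]).all():  # a contained in b
                parent[a] = b
                break
            # overlapping but not nested: not a laminar family
            return _canonical_key_bruteforce(X, nu)
        # disjoint from all previous -> stays at root
    children: dict[int, list[int]] = {}
    for a, p in enumerate(parent):
        children.setdefault(p, []).append(a)

    # attach each row at its deepest containing support
    leaf_at: dict[int, int] = {}
    for i in range(r):
        best, best_size = -1, r + 1
        for a, sup in enumerate(sup_sets):
            if sup[i] and int(sup.sum()) < best_size:
                best, best_size = a, int(sup.sum())
        leaf_at[i] = best

    def code(node: int):
        kids = tuple(sorted(code(k) for k in children.get(node, [])))
        leaves = tuple(sorted(int(nu[i]) for i, a in leaf_at.items() if a == node))
        m = mults[node] if node >= 0 else 0
        return (m, leaves, kids)

    return code(-1)


def _canonical_key_bruteforce(X: np.ndarray, nu: np.ndarray):
    from itertools import permutations

    r = X.shape[0]
    if r > 9:
        raise DataValidationError(
            "cannot canonicalise a non-laminar configuration with more than 9 rows"
        )
    best = None
    for perm in permutations(range(r)):
        Xp = X[list(perm)]
        cols = tuple(sorted(tuple(int(v) for v in Xp[:, j]) for j in range(X.shape[1])))
        cand = (tuple(int(nu[i]) for i in perm), cols)
        if best is None or cand < best:
            best = cand
    return ("bf", best)
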