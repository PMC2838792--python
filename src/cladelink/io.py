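"""Core domain types and file I/O.

Reads and writes the plain-text formats used throughout the package:

* LINKAGE-style pre-makeped pedigree files (``.ped``): whitespace-delimited
  ``family id father mother sex affection`` followed by two allele columns per
  marker, ``0`` meaning missing.
* genetic map files: ``chrom name position_cM alleles`` per line, where
  ``alleles`` is either ``.`` (frequencies to be estimated from founders) or a
  comma-separated ``allele:freq`` list.
* trait matrices: TSV with ``family_id``, ``individual_id`` key columns and one
  column per behavioral symptom; states are 0/1 (dichotomous) or 0..3
  (four-state ordinal severity scales), blank or ``NA`` for missing.
* diagnosis label tables: TSV ``family_id individual_id diagnosis``.

Individuals are identified globally by ``"family_id:individual_id"`` tokens
(the *uid*), since LINKAGE ids are only unique within a family.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CladelinkError",
    "FormatError",
    "StructureError",
    "Individual",
    "Pedigree",
    "Marker",
    "GeneticMap",
    "GenotypeTable",
    "TraitMatrix",
    "MendelianError",
    "read_ped",
    "write_ped",
    "read_map",
    "write_map",
    "read_traits",
    "write_traits",
    "read_diagnoses",
    "write_diagnoses",
    "mendelian_errors",
    "estimate_founder_allele_freqs",
    "uid",
]

MISSING = 0  # PED missing token for parent / sex / allele


class CladelinkError(Exception):
    """Base class for all package errors."""


class FormatError(CladelinkError):
    """Malformed input file."""


class StructureError(CladelinkError):
    """Structurally invalid pedigree (unknown parent, cycle, disconnection)."""


def uid(family_id: str, individual_id: str) -> str:
    """Global individual identifier ``family:individual``."""
    return f"{family_id}:{individual_id}"


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders (both or neither must
    be given). ``affection`` carries the PED file's default phenotype column
    (0 unknown / 1 unaffected / 2 affected); clade-derived affection codings
    replace it during linkage. ``diagnosis`` is an optional clinical category
    label.
    """

    family_id: str
    id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"
    affection: int = 0
    diagnosis: str | None = None

    def __post_init__(self):
        if (self.father_id is None) != (self.mother_id is None):
            raise StructureError(
                f"individual {self.uid}: father and mother must both be "
                "present or both be absent"
            )

    @property
    def uid(self) -> str:
        return uid(self.family_id, self.id)

    @property
    def is_founder(self) -> bool:
        return self.father_id is None

    @property
    def father_uid(self) -> str | None:
        return None if self.father_id is None else uid(self.family_id, self.father_id)

    @property
    def mother_uid(self) -> str | None:
        return None if self.mother_id is None else uid(self.family_id, self.mother_id)


class Pedigree:
    """A collection of families with validated parent links.

    Validation enforces: parents exist within the same family, no individual is
    its own ancestor, and each family forms a single connected graph through
    parent-child edges.
    """

    def __init__(self, individuals: Sequence[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self._by_uid: dict[str, Individual] = {}
        self.families: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            if ind.uid in self._by_uid:
                raise StructureError(f"duplicate individual {ind.uid}")
            self._by_uid[ind.uid] = ind
            self.families.setdefault(ind.family_id, []).append(ind)
        self._validate()

    def _validate(self) -> None:
        for ind in self.individuals:
            for parent_uid, role in ((ind.father_uid, "father"), (ind.mother_uid, "mother")):
                if parent_uid is not None and parent_uid not in self._by_uid:
                    raise StructureError(
                        f"individual {ind.uid}: unknown {role} {parent_uid}"
                    )
        # acyclicity by iterative ancestor walk with visitation marking
        state: dict[str, int] = {}  # 0=in progress, 1=done

        for start in self._by_uid:
            stack = [(start, False)]
            while stack:
                u, processed = stack.pop()
                if processed:
                    state[u] = 1
                    continue
                if state.get(u) == 1:
                    continue
                if state.get(u) == 0:
                    raise StructureError(f"cyclic pedigree involving {u}")
                state[u] = 0
                stack.append((u, True))
                ind = self._by_uid[u]
                for p in (ind.father_uid, ind.mother_uid):
                    if p is not None and state.get(p) != 1:
                        if state.get(p) == 0:
                            raise StructureError(f"cyclic pedigree involving {p}")
                        stack.append((p, False))
        # per-family connectivity via union-find on parent-child edges
        for fam, members in self.families.items():
            if len(members) == 1:
                continue
            parent = {m.uid: m.uid for m in members}

            def find(x: str) -> str:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for m in members:
                for p in (m.father_uid, m.mother_uid):
                    if p is not None:
                        parent[find(m.uid)] = find(p)
            roots = {find(m.uid) for m in members}
            if len(roots) > 1:
                raise StructureError(f"family {fam} is not connected")

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, u: str) -> bool:
        return u in self._by_uid

    def __getitem__(self, u: str) -> Individual:
        return self._by_uid[u]

    @property
    def uids(self) -> list[str]:
        return [i.uid for i in self.individuals]

    def founders(self, family_id: str | None = None) -> list[Individual]:
        pool = self.individuals if family_id is None else self.families[family_id]
        return [i for i in pool if i.is_founder]

    def children_of(self, family_id: str) -> dict[tuple[str, str], list[Individual]]:
        """Group a family's non-founders by (father_uid, mother_uid) couple."""
        out: dict[tuple[str, str], list[Individual]] = {}
        for ind in self.families[family_id]:
            if not ind.is_founder:
                out.setdefault((ind.father_uid, ind.mother_uid), []).append(ind)
        return out

    def with_diagnoses(self, labels: Mapping[str, str]) -> "Pedigree":
        """Return a copy with diagnosis labels attached (keyed by uid)."""
        new = [
            Individual(
                i.family_id, i.id, i.father_id, i.mother_id, i.sex, i.affection,
                labels.get(i.uid, i.diagnosis),
            )
            for i in self.individuals
        ]
        return Pedigree(new)


@dataclass(frozen=True)
class Marker:
    """A microsatellite marker on the genetic map.

    Allele labels are positive integers as in LINKAGE files. ``freqs`` holds
    population allele frequencies in label order, or ``None`` when they are to
    be estimated from typed founders.
    """

    name: str
    chrom: str
    pos_cm: float
    alleles: tuple[int, ...]
    freqs: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.freqs is not None:
            if len(self.freqs) != len(self.alleles):
                raise FormatError(f"marker {self.name}: allele/frequency length mismatch")
            if abs(sum(self.freqs) - 1.0) > 1e-9:
                raise FormatError(f"marker {self.name}: allele frequencies do not sum to 1")


class GeneticMap:
    """Ordered markers per chromosome with strictly increasing cM positions."""

    def __init__(self, markers: Sequence[Marker]):
        self.markers: list[Marker] = list(markers)
        self.by_chrom: dict[str, list[Marker]] = {}
        self._index: dict[str, int] = {}
        for i, m in enumerate(self.markers):
            if m.name in self._index:
                raise FormatError(f"duplicate marker name {m.name}")
            self._index[m.name] = i
            self.by_chrom.setdefault(m.chrom, []).append(m)
        for chrom, ms in self.by_chrom.items():
            pos = [m.pos_cm for m in ms]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise FormatError(f"chromosome {chrom}: positions not strictly increasing")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, name: str) -> Marker:
        return self.markers[self._index[name]]

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def with_freqs(self, freqs: Mapping[str, Sequence[float]]) -> "GeneticMap":
        new = [
            Marker(m.name, m.chrom, m.pos_cm, m.alleles, tuple(freqs[m.name]))
            if m.name in freqs else m
            for m in self.markers
        ]
        return GeneticMap(new)


class GenotypeTable:
    """Unordered allele pairs per (individual, marker); 0 encodes missing.

    Backed by an ``(n_individuals, n_markers, 2)`` int16 array; allele values
    are the map's integer labels. Either both alleles of a pair are typed or
    both are missing.
    """

    def __init__(self, uids: Sequence[str], gmap: GeneticMap,
                 data: np.ndarray | None = None):
        self.uids = list(uids)
        self.gmap = gmap
        self._row = {u: i for i, u in enumerate(self.uids)}
        if data is None:
            data = np.zeros((len(self.uids), len(gmap), 2), dtype=np.int16)
        data = np.asarray(data, dtype=np.int16)
        if data.shape != (len(self.uids), len(gmap), 2):
            raise FormatError("genotype array shape mismatch")
        self.data = data

    def get(self, u: str, marker: str) -> tuple[int, int] | None:
        a, b = self.data[self._row[u], self.gmap.index(marker)]
        if a == MISSING or b == MISSING:
            return None
        return (int(a), int(b)) if a <= b else (int(b), int(a))

    def set(self, u: str, marker: str, pair: tuple[int, int] | None) -> None:
        j = self.gmap.index(marker)
        self.data[self._row[u], j] = (0, 0) if pair is None else pair

    def typed_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_markers) mask of fully typed genotype cells."""
        return (self.data != MISSING).all(axis=2)

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(self.uids, self.gmap, self.data.copy())

    def row(self, u: str) -> int:
        return self._row[u]


DICHOTOMOUS = "dichotomous"
ORDINAL4 = "ordinal4"


class TraitMatrix:
    """Individuals x behavioral symptoms with missing values.

    Wraps a float DataFrame indexed by uid (NaN = missing). Each column is
    either dichotomous (states 0/1) or a four-state ordinal severity scale
    (states 0..3). The kind is inferred from the observed states unless
    supplied explicitly.
    """

    def __init__(self, frame: pd.DataFrame, trait_kinds: Mapping[str, str] | None = None):
        frame = frame.astype(float)
        self.frame = frame
        if trait_kinds is None:
            trait_kinds = {}
            for col in frame.columns:
                vals = set(frame[col].dropna().unique())
                if not vals <= {0.0, 1.0, 2.0, 3.0}:
                    bad = sorted(vals - {0.0, 1.0, 2.0, 3.0})
                    raise FormatError(f"trait {col}: states outside 0..3: {bad}")
                trait_kinds[col] = ORDINAL4 if vals & {2.0, 3.0} else DICHOTOMOUS
        self.trait_kinds = dict(trait_kinds)
        for col in frame.columns:
            vals = set(frame[col].dropna().unique())
            allowed = {0.0, 1.0} if self.trait_kinds[col] == DICHOTOMOUS else {0.0, 1.0, 2.0, 3.0}
            if not vals <= allowed:
                raise FormatError(f"trait {col}: states {sorted(vals)} invalid for "
                                  f"{self.trait_kinds[col]}")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.frame.columns)

    def states(self) -> np.ndarray:
        """int8 matrix with -1 for missing."""
        arr = self.frame.to_numpy()
        out = np.where(np.isnan(arr), -1, arr).astype(np.int8)
        return out

    def is_scored(self, u: str) -> bool:
        return u in self.frame.index

    def subset(self, uids: Iterable[str]) -> "TraitMatrix":
        keep = [u for u in uids if u in self.frame.index]
        return TraitMatrix(self.frame.loc[keep], self.trait_kinds)

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# PED I/O

_SEX_IN = {"1": "male", "2": "female", "0": "unknown"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


def read_ped(path: str | Path, gmap: GeneticMap) -> tuple[Pedigree, GenotypeTable]:
    """Read a pre-makeped LINKAGE pedigree file.

    Columns: family, individual, father, mother, sex, affection, then two
    allele columns per marker in map order; ``0`` is missing throughout.

    Raises
    ------
    FormatError
        Wrong column count, non-integer allele, or allele absent from the
        marker's label set.
    StructureError
        Unknown parent, cyclic pedigree, or disconnected family.
    """
    n_mark = len(gmap)
    inds: list[Individual] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_mark:
                raise FormatError(
                    f"{path}:{lineno}: expected {6 + 2 * n_mark} columns, got {len(tok)}"
                )
            fam, iid, fa, mo, sex, aff = tok[:6]
            if sex not in _SEX_IN:
                raise FormatError(f"{path}:{lineno}: bad sex code {sex!r}")
            try:
                aff_i = int(aff)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: bad affection {aff!r}") from e
            inds.append(Individual(
                fam, iid,
                None if fa == "0" else fa,
                None if mo == "0" else mo,
                _SEX_IN[sex], aff_i,
            ))
            try:
                alleles = np.array([int(t) for t in tok[6:]], dtype=np.int16)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-integer allele") from e
            pairs = alleles.reshape(n_mark, 2)
            for j, m in enumerate(gmap):
                a, b = pairs[j]
                if (a == 0) != (b == 0):
                    raise FormatError(
                        f"{path}:{lineno}: half-missing genotype at {m.name}")
                for al in (a, b):
                    if al != 0 and int(al) not in m.alleles:
                        raise FormatError(
                            f"{path}:{lineno}: allele {al} not in map for {m.name}")
            rows.append(pairs)
    ped = Pedigree(inds)
    data = np.stack(rows) if rows else np.zeros((0, n_mark, 2), dtype=np.int16)
    return ped, GenotypeTable([i.uid for i in inds], gmap, data)


def write_ped(path: str | Path, ped: Pedigree, genotypes: GenotypeTable) -> None:
    with open(path, "w") as fh:
        for ind in ped.individuals:
            row = genotypes.data[genotypes.row(ind.uid)]
            tok = [ind.family_id, ind.id, ind.father_id or "0", ind.mother_id or "0",
                   _SEX_OUT[ind.sex], str(ind.affection)]
            tok += [str(int(a)) for a in row.ravel()]
            fh.write(" ".join(tok) + "\n")


def read_map(path: str | Path) -> GeneticMap:
    """Read a map file: ``chrom name pos_cM alleles`` per line.

    ``alleles`` is ``a1:f1,a2:f2,...`` or ``a1,a2,...`` (labels only) or ``.``
    (labels 1/2 with frequencies to be estimated).
    """
    markers: list[Marker] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if len(tok) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, name, pos, allele_spec = tok
            if allele_spec == ".":
                alleles, freqs = (1, 2), None
            else:
                parts = allele_spec.split(",")
                if ":" in parts[0]:
                    alleles = tuple(int(p.split(":")[0]) for p in parts)
                    freqs = tuple(float(p.split(":")[1]) for p in parts)
                else:
                    alleles, freqs = tuple(int(p) for p in parts), None
            markers.append(Marker(name, chrom, float(pos), alleles, freqs))
    return GeneticMap(markers)


def write_map(path: str | Path, gmap: GeneticMap) -> None:
    with open(path, "w") as fh:
        for m in gmap:
            if m.freqs is None:
                spec = ",".join(str(a) for a in m.alleles)
            else:
                spec = ",".join(f"{a}:{f:g}" for a, f in zip(m.alleles, m.freqs))
            fh.write(f"{m.chrom} {m.name} {m.pos_cm:g} {spec}\n")


def read_traits(path: str | Path) -> TraitMatrix:
    """Read a TSV trait matrix keyed by ``family_id``, ``individual_id``."""
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "individual_id": str},
                     na_values=["NA", ""])
    for key in ("family_id", "individual_id"):
        if key not in df.columns:
            raise FormatError(f"{path}: missing key column {key}")
    idx = [uid(f, i) for f, i in zip(df["family_id"], df["individual_id"])]
    body = df.drop(columns=["family_id", "individual_id"])
    body.index = idx
    return TraitMatrix(body)


def write_traits(path: str | Path, traits: TraitMatrix) -> None:
    df = traits.frame.copy()
    fam = [u.split(":", 1)[0] for u in df.index]
    ind = [u.split(":", 1)[1] for u in df.index]
    out = pd.DataFrame({"family_id": fam, "individual_id": ind})
    for col in df.columns:
        out[col] = [("" if np.isnan(v) else str(int(v))) for v in df[col]]
    out.to_csv(path, sep="\t", index=False)


def read_diagnoses(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("family_id", "individual_id", "diagnosis"):
        if key not in df.columns:
            raise FormatError(f"{path}: missing column {key}")
    return {uid(f, i): d for f, i, d in
            zip(df["family_id"], df["individual_id"], df["diagnosis"])}


def write_diagnoses(path: str | Path, labels: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tindividual_id\tdiagnosis\n")
        for u, d in labels.items():
            fam, ind = u.split(":", 1)
            fh.write(f"{fam}\t{ind}\t{d}\n")


# ---------------------------------------------------------------------------
# Genotype checks and founder frequencies

@dataclass(frozen=True)
class MendelianError:
    family_id: str
    marker: str
    child_uid: str


def mendelian_errors(ped: Pedigree, genotypes: GenotypeTable) -> list[MendelianError]:
    """All (family, marker, child) transmission inconsistencies.

    A child is inconsistent at a marker when no assignment of one allele from
    the father's pair and one from the mother's pair reproduces the child's
    pair. Missing genotypes are unconstrained.
    """
    out: list[MendelianError] = []
    for ind in ped.individuals:
        if ind.is_founder:
            continue
        for m in genotypes.gmap:
            child = genotypes.get(ind.uid, m.name)
            if child is None:
                continue
            fa = genotypes.get(ind.father_uid, m.name)
            mo = genotypes.get(ind.mother_uid, m.name)
            fa_opts = fa if fa is not None else m.alleles
            mo_opts = mo if mo is not None else m.alleles
            ok = any(tuple(sorted((a, b))) == child for a in fa_opts for b in mo_opts)
            if not ok:
                out.append(MendelianError(ind.family_id, m.name, ind.uid))
    return out


def estimate_founder_allele_freqs(ped: Pedigree, genotypes: GenotypeTable,
                                  marker: str) -> np.ndarray:
    """Allele frequencies from typed founders, in map allele-label order.

    Raises :class:`CladelinkError` when no founder is typed at the marker, in
    which case frequencies must be supplied via the map file.
    """
    m = genotypes.gmap[marker]
    counts = np.zeros(len(m.alleles), dtype=float)
    label_pos = {a: i for i, a in enumerate(m.alleles)}
    for f in ped.founders():
        g = genotypes.get(f.uid, marker)
        if g is None:
            continue
        counts[label_pos[g[0]]] += 1
        counts[label_pos[g[1]]] += 1
    if counts.sum() == 0:
        raise CladelinkError(
            f"marker {marker}: no typed founders; supply allele frequencies in the map"
        )
    return counts / counts.sum()


def marker_freqs(ped: Pedigree, genotypes: GenotypeTable, marker: str) -> np.ndarray:
    """Map-file frequencies when present, else founder-estimated."""
    m = genotypes.gmap[marker]
    if m.freqs is not None:
        return np.asarray(m.freqs, dtype=float)
    return estimate_founder_allele_freqs(ped, genotypes, marker)
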