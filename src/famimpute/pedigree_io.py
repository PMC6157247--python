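"""Pedigree parsing and genetic relationship matrices.

Reads PLINK-style ``.fam``/``.ped`` pedigree files and computes the pairwise
genetic relationship matrix phi used throughout the package.  phi follows the
numerator-relationship convention: phi[i, j] is twice the kinship coefficient,
so a non-inbred individual has phi[i, i] = 1 and a parent-offspring pair has
phi = 0.5.  With this convention the additive variance component Sigma_A is
directly the additive-genetic covariance of the phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_PARENT = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, dangling parents, ...)."""


@dataclass(frozen=True)
class Individual:
    iid: str
    fid: str
    father: str | None = None
    mother: str | None = None
    sex: str | None = None


@dataclass
class Pedigree:
    """A validated set of individuals with family and parent links.

    Invariants enforced at construction: parent links resolve within the
    pedigree (founders have both links missing), the parent graph is acyclic,
    and ids are unique.  Individuals keep their input order.
    """

    individuals: list[Individual]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [ind.iid for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate individual ids: {dup}")
        object.__setattr__(self, "_index", {iid: k for k, iid in enumerate(ids)})
        idset = set(ids)
        for ind in self.individuals:
            for role, pid in (("father", ind.father), ("mother", ind.mother)):
                if pid is not None and pid not in idset:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.iid!r} is not in the pedigree"
                    )
                if pid is not None:
                    parent = self.individuals[self._index[pid]]
                    if parent.fid != ind.fid:
                        raise PedigreeError(
                            f"{ind.iid!r} links parent {pid!r} in a different family"
                        )
        self.topological_order()  # raises on cycles

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.iid for ind in self.individuals]

    @property
    def family_ids(self) -> list[str]:
        return sorted({ind.fid for ind in self.individuals})

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[self._index[iid]]

    def is_founder(self, iid: str) -> bool:
        ind = self[iid]
        return ind.father is None and ind.mother is None

    @property
    def founders(self) -> list[str]:
        return [i.iid for i in self.individuals if i.father is None and i.mother is None]

    def topological_order(self) -> list[str]:
        """Ids ordered parents-before-children (Kahn's algorithm).

        Raises :class:`PedigreeError` if the parent graph has a cycle
        (e.g. an individual listed as its own ancestor).
        """
        children: dict[str, list[str]] = {i.iid: [] for i in self.individuals}
        indeg = {i.iid: 0 for i in self.individuals}
        for ind in self.individuals:
            for pid in (ind.father, ind.mother):
                if pid is not None:
                    children[pid].append(ind.iid)
                    indeg[ind.iid] += 1
        queue = [iid for iid, d in indeg.items() if d == 0]
        order: list[str] = []
        while queue:
            iid = queue.pop()
            order.append(iid)
            for child in children[iid]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if len(order) != len(self.individuals):
            bad = sorted(iid for iid, d in indeg.items() if d > 0)
            raise PedigreeError(f"pedigree contains a cycle involving {bad}")
        return order


@dataclass
class RelationshipMatrix:
    """Genetic relationship (numerator) matrix over an ordered id list.

    Symmetric PSD; diagonal 1 for non-inbred individuals; zero between
    members of different families when pedigree-derived.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        """Restriction to ``ids`` in the given order (e.g. the phenotyped sample)."""
        pos = {iid: k for k, iid in enumerate(self.ids)}
        try:
            idx = np.array([pos[i] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} not in relationship matrix") from None
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )

    @classmethod
    def from_tsv(cls, path) -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def read_pedigree(path, dialect: str = "fam", on_missing_parent: str = "fail") -> Pedigree:
    """Read a PLINK-style pedigree file.

    Parameters
    ----------
    path
        Whitespace- or tab-delimited file.  ``fam`` expects the 6 PLINK
        columns (FID IID PAT MAT SEX PHENO); ``ped`` uses the same leading 6
        columns and ignores any trailing genotype columns.  Missing parents
        are coded ``"0"``.
    on_missing_parent
        ``"fail"`` (default) rejects parent ids absent from the file;
        ``"create"`` silently adds them as founders of the same family.
    """
    if dialect not in ("fam", "ped"):
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    if on_missing_parent not in ("fail", "create"):
        raise ValueError(f"on_missing_parent must be 'fail' or 'create'")
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 4:
        raise PedigreeError(
            f"{path}: expected at least 4 columns (FID IID PAT MAT), got {df.shape[1]}"
        )
    individuals: list[Individual] = []
    seen: set[str] = set()
    fam_of: dict[str, str] = {}
    referenced: list[tuple[str, str]] = []  # (parent_id, family)
    for row in df.itertuples(index=False):
        fid, iid, pat, mat = str(row[0]), str(row[1]), str(row[2]), str(row[3])
        sex = str(row[4]) if df.shape[1] >= 5 else None
        father = None if pat == MISSING_PARENT else pat
        mother = None if mat == MISSING_PARENT else mat
        individuals.append(Individual(iid=iid, fid=fid, father=father, mother=mother, sex=sex))
        seen.add(iid)
        fam_of[iid] = fid
        for pid in (father, mother):
            if pid is not None:
                referenced.append((pid, fid))
    missing = [(pid, fid) for pid, fid in referenced if pid not in seen]
    if missing:
        if on_missing_parent == "fail":
            names = sorted({pid for pid, _ in missing})
            raise PedigreeError(
                f"parents referenced but absent from {path}: {names} "
                "(pass on_missing_parent='create' to add them as founders)"
            )
        added: set[str] = set()
        for pid, fid in missing:
            if pid not in added:
                individuals.append(Individual(iid=pid, fid=fid))
                added.add(pid)
    return Pedigree(individuals)


def compute_phi(ped: Pedigree) -> RelationshipMatrix:
    """Pedigree-based relationship matrix, twice the kinship coefficient.

    Kinship follows the standard recursion over a parents-before-children
    ordering: k(i, i) = (1 + k(father(i), mother(i))) / 2 and, for i != j with
    i below j in the ordering, k(i, j) = (k(father(i), j) + k(mother(i), j)) / 2;
    founders are mutually unrelated.  Inbred pedigrees are handled (the
    diagonal then exceeds 1).
    """
    order = ped.topological_order()
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    kin = np.zeros((n, n))
    for i, iid in enumerate(order):
        ind = ped[iid]
        fi = pos[ind.father] if ind.father is not None else None
        mi = pos[ind.mother] if ind.mother is not None else None
        if fi is None and mi is None:
            # founder: no shared ancestry with anyone placed before it
            kin[i, i] = 0.5
            continue
        kf_m = kin[fi, mi] if (fi is not None and mi is not None) else 0.0
        kin[i, i] = 0.5 * (1.0 + kf_m)
        if i > 0:  # earlier individuals are never descendants of i
            kf = kin[fi, :i] if fi is not None else 0.0
            km = kin[mi, :i] if mi is not None else 0.0
            row = 0.5 * (kf + km)
            kin[i, :i] = row
            kin[:i, i] = row
    # reorder to the pedigree's input id order
    perm = np.array([pos[iid] for iid in ped.ids], dtype=int)
    phi = 2.0 * kin[np.ix_(perm, perm)]
    return RelationshipMatrix(ped.ids, phi)


def empirical_phi(
    dosages: np.ndarray,
    ids: list[str],
    min_maf: float = 0.01,
    min_variants: int = 200,
) -> RelationshipMatrix:
    """Genotype-based relationship estimate from an additive dosage matrix.

    Parameters
    ----------
    dosages
        Array of shape (n_variants, n_samples) with entries in [0, 2].

    Each variant is standardized by its sample allele frequency,
    z = (x - 2p) / sqrt(2p(1-p)), and the raw estimate is Z'Z / m.  The
    matrix is then rescaled to correlation form, phi_ij = G_ij /
    sqrt(G_ii G_jj), which forces the diagonal to exactly 1 — convenient for
    downstream use where phi plays the role of a correlation, at the price of
    absorbing individual-level deviations (e.g. inbreeding) into the scale.
    """
    X = np.asarray(dosages, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(ids):
        raise ValueError("dosages must be (n_variants, n_samples) matching ids")
    p = X.mean(axis=1) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf > min_maf
    if not np.any(maf > 0):
        raise ValueError("all variants are monomorphic; cannot estimate relatedness")
    if keep.sum() < min_variants:
        warnings.warn(
            f"only {int(keep.sum())} variants with MAF > {min_maf}; "
            f"empirical relatedness is noisy below {min_variants}",
            stacklevel=2,
        )
        keep = maf > 0
    Z = (X[keep] - 2.0 * p[keep, None]) / np.sqrt(2.0 * p[keep, None] * (1.0 - p[keep, None]))
    G = Z.T @ Z / keep.sum()
    d = np.sqrt(np.clip(np.diag(G), 1e-12, None))
    phi = G / np.outer(d, d)
    phi = 0.5 * (phi + phi.T)
    np.fill_diagonal(phi, 1.0)
    return RelationshipMatrix(list(ids), phi)
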