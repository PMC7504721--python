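"""Screening-library model: compounds, fragment-likeness, similarity.

A fragment library is represented as a list of :class:`Compound` records
carrying the physicochemical descriptors that the downstream triage needs
(molecular weight for theoretical-Rmax normalization, heavy-atom count for
ligand efficiency, H-bond donors and clogP for rule-of-three profiling) and
optionally a SMILES string for similarity analysis.

Similarity uses atom-pair fingerprints (rdkit backend) with the Tanimoto
coefficient computed here on the raw count vectors, so the statistic is
testable independently of the fingerprinting backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

# gas constant in kcal mol^-1 K^-1, the conventional unit for ligand efficiency
R_KCAL = 0.0019872
STANDARD_TEMPERATURE_K = 298.15


class Sublibrary(str, Enum):
    """The five library subsets: 2D/3D fragments, natural-product scaffolds,
    serine-protease-inhibitor-like and protein-protein-interaction-inhibitor
    compounds."""

    TWO_D = "2D-FL"
    THREE_D = "3D-FL"
    NPB = "NPB"
    SPI = "SPI"
    PPI = "PPI"


@dataclass(frozen=True)
class Compound:
    """One library member.

    Parameters
    ----------
    id : str
        Unique compound identifier (e.g. ``CMP-1611``).
    sublibrary : Sublibrary
        Which of the five library subsets the compound came from.
    mw : float
        Molecular weight in Da; must be positive (it scales the
        theoretical maximal SPR response).
    heavy_atoms, hbd, clogp : optional descriptors
        Heavy-atom count, H-bond donor count and calculated logP.
    smiles : optional str
        Structure for fingerprint-based similarity.
    """

    id: str
    sublibrary: Sublibrary
    mw: float
    heavy_atoms: int | None = None
    hbd: int | None = None
    clogp: float | None = None
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if not np.isfinite(self.mw) or self.mw <= 0:
            raise ValueError(f"{self.id}: non-positive molecular weight")
        if self.heavy_atoms is not None and self.heavy_atoms < 1:
            raise ValueError(f"{self.id}: heavy_atoms must be >= 1")


@dataclass(frozen=True)
class RuleOfThree:
    """Per-criterion fragment-likeness verdict (MW <= 300 Da, HBD <= 3,
    clogP <= 3; boundaries inclusive). ``indeterminate`` is set when a
    descriptor is missing — a compound is never silently compliant."""

    mw_ok: bool | None
    hbd_ok: bool | None
    clogp_ok: bool | None

    @property
    def indeterminate(self) -> bool:
        return None in (self.mw_ok, self.hbd_ok, self.clogp_ok)

    @property
    def compliant(self) -> bool:
        if self.indeterminate:
            return False
        return bool(self.mw_ok and self.hbd_ok and self.clogp_ok)

    @property
    def failing(self) -> tuple[str, ...]:
        names = ("mw", "hbd", "clogp")
        flags = (self.mw_ok, self.hbd_ok, self.clogp_ok)
        return tuple(n for n, ok in zip(names, flags) if ok is False)


@dataclass
class SimilarityMatrix:
    """Symmetric Tanimoto matrix over an ordered id list, entries in [0, 1]."""

    ids: list[str]
    values: np.ndarray
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape does not match id list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("Tanimoto values must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


class LibraryError(ValueError):
    """Raised when a compound table cannot be validated; carries a per-row
    report in ``rejected``."""

    def __init__(self, message: str, rejected: list[tuple[object, str]]):
        super().__init__(message)
        self.rejected = rejected


def load_library(table: pd.DataFrame, *, strict: bool = True) -> list[Compound]:
    """Validate a compound table into :class:`Compound` records.

    Required columns: ``id``, ``sublibrary``, ``mw``; optional:
    ``heavy_atoms``, ``hbd``, ``clogp``, ``smiles``. Duplicate ids are an
    error. With ``strict=False`` invalid rows are dropped and reported on
    the returned list's ``rejected`` attribute instead of raising.
    """
    required = {"id", "sublibrary", "mw"}
    missing = required - set(table.columns)
    if missing:
        raise LibraryError(f"missing required columns: {sorted(missing)}", [])

    dup = table["id"][table["id"].duplicated()].tolist()
    if dup:
        raise LibraryError(f"duplicate compound ids: {sorted(set(map(str, dup)))}", [])

    compounds: list[Compound] = []
    rejected: list[tuple[object, str]] = []
    for row in table.itertuples(index=False):
        d = row._asdict()
        try:
            mw = float(d["mw"])
            if not np.isfinite(mw) or mw <= 0:
                raise ValueError("non-positive molecular weight")
            c = Compound(
                id=str(d["id"]),
                sublibrary=Sublibrary(str(d["sublibrary"])),
                mw=mw,
                heavy_atoms=_opt_int(d.get("heavy_atoms")),
                hbd=_opt_int(d.get("hbd")),
                clogp=_opt_float(d.get("clogp")),
                smiles=_opt_str(d.get("smiles")),
            )
        except ValueError as exc:
            rejected.append((d.get("id"), str(exc)))
            continue
        compounds.append(c)

    if rejected and strict:
        raise LibraryError(
            f"{len(rejected)} row(s) failed validation: {rejected[:5]}", rejected
        )
    out = _CompoundList(compounds)
    out.rejected = rejected
    return out


class _CompoundList(list):
    rejected: list[tuple[object, str]] = []


def _opt_int(v) -> int | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return int(v)


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    s = str(v)
    return s if s else None


def rule_of_three(c: Compound) -> RuleOfThree:
    """Fragment-likeness filter: MW <= 300 Da, H-bond donors <= 3 and
    clogP <= 3, all boundaries inclusive. Missing descriptors leave the
    corresponding criterion ``None`` and the verdict indeterminate."""
    return RuleOfThree(
        mw_ok=None if c.mw is None else c.mw <= 300.0,
        hbd_ok=None if c.hbd is None else c.hbd <= 3,
        clogp_ok=None if c.clogp is None else c.clogp <= 3.0,
    )


def ligand_efficiency(
    kd: float, heavy_atoms: int, temperature: float = STANDARD_TEMPERATURE_K
) -> float:
    """Binding free energy per heavy atom, LE = -RT ln(K_D) / HAC.

    ``kd`` is the equilibrium dissociation constant in molar; the result is
    in kcal mol^-1 per heavy atom and positive for sub-molar binders.
    """
    if kd <= 0 or not np.isfinite(kd):
        raise ValueError("kd must be a positive, finite molar concentration")
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return -R_KCAL * temperature * float(np.log(kd)) / heavy_atoms


def tanimoto(a: Mapping[int, int] | Iterable[int], b: Mapping[int, int] | Iterable[int]) -> float:
    """Tanimoto coefficient on fingerprint sets or count vectors.

    For sets, |A & B| / |A | B|; for count mappings, sum(min)/sum(max) (the
    count-vector generalization). Two empty fingerprints give 0.
    """
    if isinstance(a, Mapping) or isinstance(b, Mapping):
        ca = dict(a) if isinstance(a, Mapping) else {k: 1 for k in a}
        cb = dict(b) if isinstance(b, Mapping) else {k: 1 for k in b}
        keys = set(ca) | set(cb)
        num = sum(min(ca.get(k, 0), cb.get(k, 0)) for k in keys)
        den = sum(max(ca.get(k, 0), cb.get(k, 0)) for k in keys)
    else:
        sa, sb = set(a), set(b)
        num = len(sa & sb)
        den = len(sa | sb)
    return num / den if den else 0.0


def atom_pair_fingerprint(smiles: str) -> dict[int, int] | None:
    """Atom-pair count fingerprint via rdkit; None for unparsable SMILES."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    gen = rdFingerprintGenerator.GetAtomPairGenerator()
    return dict(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())


def tanimoto_matrix(compounds: Sequence[Compound]) -> SimilarityMatrix:
    """Pairwise atom-pair Tanimoto matrix over compounds carrying SMILES.

    Compounds with missing or unparsable SMILES are excluded and listed on
    ``SimilarityMatrix.excluded``; the matrix is built on the remainder.
    """
    fps: dict[str, dict[int, int]] = {}
    excluded: list[str] = []
    for c in compounds:
        fp = atom_pair_fingerprint(c.smiles) if c.smiles else None
        if fp is None:
            excluded.append(c.id)
        else:
            fps[c.id] = fp
    ids = list(fps)
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        if not fps[ids[i]]:
            values[i, i] = 0.0
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tanimoto(fps[ids[i]], fps[ids[j]])
    return SimilarityMatrix(ids=ids, values=values, excluded=excluded)


# MW ranges (Da) observed across the five subsets of the screening library
_SUBLIBRARY_MW_RANGES = {
    Sublibrary.TWO_D: (99.0, 330.0),
    Sublibrary.THREE_D: (109.0, 372.0),
    Sublibrary.NPB: (221.0, 568.0),
    Sublibrary.SPI: (164.0, 575.0),
    Sublibrary.PPI: (138.0, 580.0),
}
# subset sizes are proportioned 1:1:1:1:4 (250/250/250/250/1000 at n=2000)
_SUBLIBRARY_WEIGHTS = {
    Sublibrary.TWO_D: 1,
    Sublibrary.THREE_D: 1,
    Sublibrary.NPB: 1,
    Sublibrary.SPI: 1,
    Sublibrary.PPI: 4,
}


def synthetic_library(n: int = 2000, seed: int = 0) -> list[Compound]:
    """Generate a synthetic fragment library with the composition of the
    screening campaign: five subsets sized 1:1:1:1:4, molecular weights
    drawn uniformly from each subset's range, and plausible heavy-atom,
    H-bond-donor and clogP descriptors (MW/13.5 heavy atoms, HBD 0-4,
    clogP roughly normal around 1.5)."""
    if n < 1:
        raise ValueError("library size must be >= 1")
    rng = np.random.default_rng(seed)
    total_w = sum(_SUBLIBRARY_WEIGHTS.values())
    counts = {s: (n * w) // total_w for s, w in _SUBLIBRARY_WEIGHTS.items()}
    # hand the integer remainder to the largest subset
    counts[Sublibrary.PPI] += n - sum(counts.values())
    compounds: list[Compound] = []
    i = 0
    for sub, count in counts.items():
        lo, hi = _SUBLIBRARY_MW_RANGES[sub]
        for _ in range(count):
            i += 1
            mw = float(rng.uniform(lo, hi))
            compounds.append(Compound(
                id=f"CMP-{i}",
                sublibrary=sub,
                mw=round(mw, 1),
                heavy_atoms=max(5, int(round(mw / 13.5))),
                hbd=int(rng.integers(0, 5)),
                clogp=round(float(rng.normal(1.5, 1.2)), 2),
            ))
    return compounds


def cluster_single_linkage(sim: SimilarityMatrix, cut: float) -> dict[str, int]:
    """Single-linkage clusters of the 1 - Tanimoto distance matrix, cut at
    ``cut`` (merges strictly below the threshold stay joined; scipy's
    ``fcluster(..., criterion='distance')`` keeps merges at height <= cut).

    Returns a mapping id -> cluster label (1-based, deterministic).
    """
    n = len(sim.ids)
    if n == 0:
        raise ValueError("cannot cluster an empty similarity matrix")
    if n == 1:
        return {sim.ids[0]: 1}
    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="single")
    labels = fcluster(z, t=cut, criterion="distance")
    return {cid: int(lab) for cid, lab in zip(sim.ids, labels)}
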