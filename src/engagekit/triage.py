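"""Virtual-screen post-processing over a compound library.

Descriptors (MW, Crippen cLogP, Lipinski H-bond donors/acceptors, Ertl
TPSA), drug-likeness window filtering, combination of the two docking
ranks (minimum of HybridRank and MOERank), ECFP4 Tanimoto similarity, and
greedy sphere-exclusion diversity picking.  Docking itself is out of scope:
ranks are inputs, read from a CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator
from rdkit.Chem import rdMolDescriptors

logger = logging.getLogger(__name__)

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class Compound:
    """A library member: structure, descriptors, docking ranks, fingerprint."""

    id: str
    smiles: str
    mol: object = field(repr=False, default=None)
    mw: float = np.nan
    clogp: float = np.nan
    hbd: int = -1
    hba: int = -1
    tpsa: float = np.nan
    hybrid_rank: int | None = None
    moe_rank: int | None = None
    combined_rank: int | None = None
    fingerprint: object = field(repr=False, default=None)


def compute_descriptors(mol) -> dict:
    """Physicochemical descriptor set of a molecule.

    MW sums average atomic masses including implicit hydrogens; HBD/HBA are
    the Lipinski donor (N-H, O-H) and acceptor (N, O) counts; TPSA follows
    the Ertl fragment-contribution method and cLogP the Crippen
    atomic-contribution method.
    """
    if mol is None:
        raise ValueError("cannot compute descriptors of an unparseable structure")
    return {
        "mw": float(Descriptors.MolWt(mol)),
        "clogp": float(Crippen.MolLogP(mol)),
        "hbd": int(Lipinski.NumHDonors(mol)),
        "hba": int(Lipinski.NumHAcceptors(mol)),
        "tpsa": float(rdMolDescriptors.CalcTPSA(mol)),
    }


def ecfp4(mol, n_bits: int = 2048):
    """Circular (Morgan radius-2) fingerprint hashed to ``n_bits`` bits."""
    if n_bits == 2048:
        return _MORGAN.GetFingerprint(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return gen.GetFingerprint(mol)


def _annotate(cid: str, smiles: str, mol) -> Compound:
    comp = Compound(cid, Chem.MolToSmiles(mol), mol=mol,
                    fingerprint=ecfp4(mol), **compute_descriptors(mol))
    return comp


def parse_structures(path) -> list[Compound]:
    """Parse a SMILES file (one per line, optional id) or an SDF (V2000).

    Invalid records are skipped with a logged reason; an input yielding zero
    valid structures is an error.  Parsed structures are canonicalized and
    annotated with descriptors and ECFP4 fingerprints.
    """
    path = Path(path)
    compounds: list[Compound] = []
    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("%s: record %d skipped (unparseable)", path.name, i + 1)
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i + 1}"
            compounds.append(_annotate(cid, Chem.MolToSmiles(mol), mol))
    else:
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"smi{lineno}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                logger.warning("%s, line %d: skipped invalid SMILES %r",
                               path.name, lineno, smiles)
                continue
            compounds.append(_annotate(cid, smiles, mol))
    if not compounds:
        raise ValueError(f"{path.name}: no valid structures parsed")
    return compounds


def from_smiles(smiles: str, cid: str = "query") -> Compound:
    """Parse and annotate a single SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return _annotate(cid, smiles, mol)


# ---------------------------------------------------------------------------
# physicochemical windows

@dataclass(frozen=True)
class Window:
    """Closed/open interval for one descriptor; None = unbounded."""

    lower: float | None = None
    upper: float | None = None
    lower_inclusive: bool = True
    upper_inclusive: bool = True

    def __post_init__(self) -> None:
        if (self.lower is not None and self.upper is not None
                and self.lower > self.upper):
            raise ValueError("window lower bound exceeds upper bound")

    def contains(self, value: float) -> bool:
        if self.lower is not None:
            if value < self.lower or (value == self.lower and not self.lower_inclusive):
                return False
        if self.upper is not None:
            if value > self.upper or (value == self.upper and not self.upper_inclusive):
                return False
        return True


#: Drug-likeness windows of the virtual-screen funnel:
#: MW < 450, cLogP 1-3, H-acceptors 1-5, H-donors 1-3, TPSA < 140.
VHTS_WINDOWS: dict[str, Window] = {
    "mw": Window(upper=450, upper_inclusive=False),
    "clogp": Window(1, 3),
    "hba": Window(1, 5),
    "hbd": Window(1, 3),
    "tpsa": Window(upper=140, upper_inclusive=False),
}

#: Tighter lead-profile thresholds: MW < 350, cLogP < 3.5, HBD <= 2, TPSA < 120.
LEAD_WINDOWS: dict[str, Window] = {
    "mw": Window(upper=350, upper_inclusive=False),
    "clogp": Window(upper=3.5, upper_inclusive=False),
    "hbd": Window(upper=2),
    "tpsa": Window(upper=120, upper_inclusive=False),
}


def apply_physchem_filter(compounds, windows: dict[str, Window]
                          ) -> tuple[list[Compound], list[tuple[Compound, list[str]]]]:
    """Split a library into (pass, fail-with-reasons) against windows.

    Every failing compound lists each violated descriptor.  Filtering is
    per-compound, hence order-independent.
    """
    passed, failed = [], []
    for comp in compounds:
        reasons = [name for name, w in windows.items()
                   if not w.contains(getattr(comp, name))]
        if reasons:
            failed.append((comp, reasons))
        else:
            passed.append(comp)
    return passed, failed


# ---------------------------------------------------------------------------
# ranks

def read_rank_file(path) -> pd.DataFrame:
    """CSV of docking ranks: id, hybrid_rank, moe_rank."""
    df = pd.read_csv(path)
    required = {"id", "hybrid_rank", "moe_rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rank file missing columns: {sorted(missing)}")
    return df


def combine_ranks(compounds, ranks: pd.DataFrame | None = None
                  ) -> tuple[list[Compound], list[str]]:
    """Attach combined_rank = min(hybrid_rank, moe_rank) and sort ascending.

    Ties break by hybrid_rank, then id.  Compounds missing either rank are
    excluded and returned as logged exclusions.
    """
    if ranks is not None:
        by_id = ranks.set_index(ranks["id"].astype(str))
        for comp in compounds:
            if comp.id in by_id.index:
                comp.hybrid_rank = int(by_id.loc[comp.id, "hybrid_rank"])
                comp.moe_rank = int(by_id.loc[comp.id, "moe_rank"])
    ranked, excluded = [], []
    for comp in compounds:
        if comp.hybrid_rank is None or comp.moe_rank is None:
            logger.warning("compound %s excluded: missing docking rank", comp.id)
            excluded.append(comp.id)
            continue
        comp.combined_rank = min(comp.hybrid_rank, comp.moe_rank)
        ranked.append(comp)
    ranked.sort(key=lambda c: (c.combined_rank, c.hybrid_rank, c.id))
    return ranked, excluded


# ---------------------------------------------------------------------------
# similarity and diversity picking

def _as_bits(fp) -> np.ndarray:
    if isinstance(fp, np.ndarray):
        return fp.astype(bool)
    arr = np.zeros(fp.GetNumBits(), dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return arr.astype(bool)


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto similarity |A&B| / |A|B| of two equal-length bit sets.

    Defined as 1.0 when both fingerprints are empty.  Accepts RDKit bit
    vectors or boolean/0-1 numpy arrays.
    """
    a, b = _as_bits(fp_a), _as_bits(fp_b)
    if a.size != b.size:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b)) / union


def diversity_pick(compounds, sim_cutoff: float = 0.52,
                   max_picks: int | None = None) -> list[Compound]:
    """Greedy sphere-exclusion diversity selection over a ranked list.

    Walk the list in its (combined-rank) order; keep a compound iff its
    ECFP4 Tanimoto similarity to every previously kept compound is below
    ``sim_cutoff``.  Stops at ``max_picks``.  The kept set therefore never
    contains a pair at or above the cutoff, and each similarity cluster is
    represented by its best-ranked member.
    """
    kept: list[Compound] = []
    kept_fps: list[np.ndarray] = []
    for comp in compounds:
        fp = _as_bits(comp.fingerprint)
        if any(tanimoto(fp, k) >= sim_cutoff for k in kept_fps):
            continue
        kept.append(comp)
        kept_fps.append(fp)
        if max_picks is not None and len(kept) >= max_picks:
            break
    return kept


def triage_report(compounds, windows=VHTS_WINDOWS) -> pd.DataFrame:
    """Descriptor / window report as a tidy frame (one row per compound)."""
    rows = []
    for comp in compounds:
        reasons = [name for name, w in windows.items()
                   if not w.contains(getattr(comp, name))]
        rows.append({"id": comp.id, "smiles": comp.smiles,
                     "mw": comp.mw, "clogp": comp.clogp, "hbd": comp.hbd,
                     "hba": comp.hba, "tpsa": comp.tpsa,
                     "hybrid_rank": comp.hybrid_rank, "moe_rank": comp.moe_rank,
                     "combined_rank": comp.combined_rank,
                     "passes_filter": not reasons,
                     "fail_reasons": ";".join(reasons)})
    return pd.DataFrame(rows)
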