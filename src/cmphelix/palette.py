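"""Residue palette and the combinatorial hexamer-repeat sequence space.

Collagen-mimetic peptoids (CMPs) studied here are 18-mers built from three
repeats of a hexamer ``x1-y1-Gly-x2-y2-Gly``.  The ``x`` slots admit one of
five residues that carry a formal charge at (or near) physiological pH, the
``y`` slots one of twenty peptoid residues, and every third slot is glycine
to permit close packing of the triple helix.  The palette is shipped as a
CSV data table with one row per residue: three-letter code, one-letter code,
chemical name, formal charge at pH 7, eligible slots, hydrophobicity flags
and the side-chain SMILES fragment used to assemble molecular graphs.

The hexamer repeat unit (not the full 18-mer) is what gets fingerprinted;
:func:`sequence_to_molgraph` builds it as an RDKit molecule terminated with
an N-terminal hydrogen and a C-terminal primary amide.  This capping is a
fixed package convention chosen for reproducibility of the fingerprints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from functools import lru_cache

import pandas as pd
from rdkit import Chem

from .errors import EmptyPalette, InvalidPosition, UnknownResidue

GLY_SLOTS = (2, 5)  # zero-based positions of the obligatory glycines
X_SLOTS = (0, 3)
Y_SLOTS = (1, 4)


@dataclass(frozen=True)
class ResidueSpec:
    """One palette entry (a row of the shipped Table-1-style CSV)."""

    code3: str
    code1: str
    name: str
    charge_pH7: int
    allowed_positions: frozenset  # subset of {"x", "y"}
    sidechain_smiles: str  # fragment attached at the backbone N; "" for Gly
    hydrophobic: bool
    light_hydrophobe: bool


@dataclass(frozen=True)
class PeptoidSequence:
    """A validated hexamer-repeat code, e.g. ``EKGEKG`` for (EKGEKG)3."""

    hexamer_code: str
    n_repeats: int = 3
    flank_ppg: bool = False  # engineered PPG-flanked double-hexamer variant

    def __str__(self) -> str:
        core = f"({self.hexamer_code}){self.n_repeats}"
        return f"PPG({self.hexamer_code})2PPG" if self.flank_ppg else core


@dataclass(frozen=True)
class CompositionVector:
    """Residue counts over the four variable hexamer positions."""

    counts: dict  # one-letter code -> count, Gly slots excluded
    n_charged: int
    n_hydrophobic: int
    net_charge: int


def _default_rows() -> pd.DataFrame:
    with resources.files("cmphelix.data").joinpath("palette.csv").open() as fh:
        return pd.read_csv(fh, keep_default_na=False)


def build_palette() -> list[ResidueSpec]:
    """Load the shipped 22-residue palette (20 peptoid residues + Gly + Pro)."""
    rows = _default_rows()
    palette = []
    for _, r in rows.iterrows():
        palette.append(
            ResidueSpec(
                code3=r["code3"],
                code1=str(r["code1"]),
                name=r["name"],
                charge_pH7=int(r["charge_pH7"]),
                allowed_positions=frozenset(str(r["positions"])) - {""},
                sidechain_smiles=str(r["sidechain_smiles"]),
                hydrophobic=bool(int(r["hydrophobic"])),
                light_hydrophobe=bool(int(r["light_hydrophobe"])),
            )
        )
    codes = [p.code1 for p in palette]
    if len(set(codes)) != len(codes):
        raise EmptyPalette("duplicate one-letter codes in palette")
    return palette


@lru_cache(maxsize=1)
def _default_palette_map() -> dict:
    return {p.code1: p for p in build_palette()}


def palette_map(palette=None) -> dict:
    if palette is None:
        return _default_palette_map()
    return {p.code1: p for p in palette}


def x_eligible(palette=None) -> list[ResidueSpec]:
    return [p for p in (palette or build_palette()) if "x" in p.allowed_positions]


def y_eligible(palette=None) -> list[ResidueSpec]:
    return [p for p in (palette or build_palette()) if "y" in p.allowed_positions]


def validate_sequence(code: str, palette=None, strict: bool = True) -> PeptoidSequence:
    """Validate a 6-character hexamer code against the slot constraints.

    With ``strict`` (the default) the x slots must hold one of the five
    charged x-eligible residues and the y slots one of the twenty y-eligible
    residues, i.e. the sequence must be a member of the combinatorial design
    space.  With ``strict=False`` only glycine placement and palette
    membership are enforced, which admits reference sequences such as the
    collagen control ``PPGPPG`` that live outside the library.
    """
    if not isinstance(code, str) or len(code) != 6:
        raise InvalidPosition(f"hexamer code must have 6 characters, got {code!r}")
    pmap = palette_map(palette)
    for i in GLY_SLOTS:
        if code[i] != "G":
            raise InvalidPosition(f"slot {i + 1} must be G, got {code[i]!r}")
    for i, ch in enumerate(code):
        if ch not in pmap:
            raise UnknownResidue(f"residue {ch!r} at slot {i + 1} not in palette")
    if strict:
        for i in X_SLOTS:
            if "x" not in pmap[code[i]].allowed_positions:
                raise InvalidPosition(
                    f"residue {code[i]!r} not allowed at x slot {i + 1}"
                )
        for i in Y_SLOTS:
            if "y" not in pmap[code[i]].allowed_positions:
                raise InvalidPosition(
                    f"residue {code[i]!r} not allowed at y slot {i + 1}"
                )
    return PeptoidSequence(code)


def enumerate_library(palette=None) -> list[PeptoidSequence]:
    """All (x1, y1, x2, y2) combinations, lexicographic by hexamer code.

    The full shipped palette yields 5^2 * 20^2 = 10 000 sequences.  The
    ordering is the deterministic index used by seeds, audit logs and the
    persisted sequence lists.
    """
    palette = palette or build_palette()
    xs = sorted(p.code1 for p in x_eligible(palette))
    ys = sorted(p.code1 for p in y_eligible(palette))
    if not xs or not ys:
        raise EmptyPalette("palette must define x- and y-eligible residues")
    codes = sorted(
        f"{x1}{y1}G{x2}{y2}G"
        for x1, y1, x2, y2 in itertools.product(xs, ys, xs, ys)
    )
    return [PeptoidSequence(c) for c in codes]


# ---------------------------------------------------------------------------
# molecular graphs
# ---------------------------------------------------------------------------

def hexamer_smiles(seq: PeptoidSequence | str, palette=None) -> str:
    """SMILES of the hexamer repeat unit.

    Each residue contributes an N-substituted glycine unit ``N(R)CC(=O)``
    with the side chain R attached at the backbone nitrogen (Gly has a
    hydrogen substituent; Pro closes a pyrrolidine ring onto the alpha
    carbon).  The fragment is terminated by an N-terminal hydrogen and a
    C-terminal primary amide.  Protonation states follow the palette's pH 7
    charges: ammonium side chains for NLys/Nae, carboxylates for NAsp/NGlu,
    neutral thiol for NCys and the N-delta tautomer for NHis.
    """
    code = seq.hexamer_code if isinstance(seq, PeptoidSequence) else seq
    pmap = palette_map(palette)
    parts = []
    ring = 10  # %nn ring-closure labels, disjoint from any in the templates
    for ch in code:
        if ch not in pmap:
            raise UnknownResidue(f"residue {ch!r} not in palette")
        spec = pmap[ch]
        if spec.code1 == "G":
            parts.append("NCC(=O)")
        elif spec.sidechain_smiles == "pyrrolidine":
            parts.append(f"N%{ring:02d}CCCC%{ring:02d}C(=O)")
            ring += 1
        else:
            t = spec.sidechain_smiles
            for label in ("A", "B"):
                if "{%s}" % label in t:
                    t = t.replace("{%s}" % label, f"%{ring:02d}")
                    ring += 1
            parts.append(f"N({t})CC(=O)")
    return "".join(parts) + "N"


def sequence_to_molgraph(seq: PeptoidSequence | str, palette=None) -> Chem.Mol:
    """RDKit molecule of the hexamer repeat (heavy atoms; implicit H)."""
    smi = hexamer_smiles(seq, palette)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:  # pragma: no cover - would indicate a bad palette entry
        raise UnknownResidue(f"could not parse assembled SMILES {smi!r}")
    return mol


def canonical_smiles(seq: PeptoidSequence | str, palette=None) -> str:
    return Chem.MolToSmiles(sequence_to_molgraph(seq, palette))


def composition_vector(seq: PeptoidSequence | str, palette=None) -> CompositionVector:
    """Counts over the four variable positions plus derived descriptors.

    ``n_charged`` counts residues with nonzero formal charge at pH 7 (NCys is
    treated as neutral), ``n_hydrophobic`` uses the ten-residue hydrophobe
    set, and ``net_charge`` is the signed sum.
    """
    code = seq.hexamer_code if isinstance(seq, PeptoidSequence) else seq
    pmap = palette_map(palette)
    counts: dict = {}
    n_charged = n_hydro = net = 0
    for i in X_SLOTS + Y_SLOTS:
        ch = code[i]
        if ch not in pmap:
            raise UnknownResidue(f"residue {ch!r} not in palette")
        counts[ch] = counts.get(ch, 0) + 1
        spec = pmap[ch]
        if spec.charge_pH7 != 0:
            n_charged += 1
        if spec.hydrophobic:
            n_hydro += 1
        net += spec.charge_pH7
    return CompositionVector(counts, n_charged, n_hydro, net)
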