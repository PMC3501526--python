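"""Peptide and protein mass arithmetic.

Supports the proteoform-adduct annotation of linear-TOF peaks (cysteinylation,
Cys-Gly, glutathionylation and related sulfhydryl adducts on a free cysteine)
and fragment bookkeeping on a parent protein's residue coordinates, e.g. the
C-terminal-region fragment of rat alpha-1-macroglobulin observed at m/z 3493.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

from pyteomics import mass as _ptmass

__all__ = [
    "ADDUCT_MASSES",
    "A1M_FRAGMENT_SEQUENCE",
    "A1M_PARENT_LENGTH",
    "A1M_FRAGMENT_START",
    "A1M_FRAGMENT_END",
    "A1M_SUBUNIT_START",
    "FragmentDescriptor",
    "peptide_mass",
    "map_fragment",
]

#: Monoisotopic mass shifts (Da) of disulfide-linked thiol adducts on cysteine.
#: Each delta is the free thiol's mass minus 2H (disulfide bond formation),
#: except sulfonation which is +SO3 oxidation of the thiol.
ADDUCT_MASSES = MappingProxyType(
    {
        "cysteinyl": 119.004,
        "cys-gly": 176.026,
        "glutathionyl": 305.068,
        "sulfonation": 79.957,
        "glu-cys": 248.047,
    }
)

#: The 32-residue alpha-1-macroglobulin fragment seen at m/z 3493 in rat CSF.
A1M_FRAGMENT_SEQUENCE = "SFSYKPRAPSAEVEMTAYVLLAYLTSASSRPT"
A1M_PARENT_LENGTH = 1500
A1M_FRAGMENT_START = 1212
A1M_FRAGMENT_END = 1243
#: First residue of the known 45 kDa C-terminal subunit of the heavy chain.
A1M_SUBUNIT_START = 1245

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _validate_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("peptide sequence must be non-empty")
    for i, aa in enumerate(seq):
        if aa not in _VALID_RESIDUES:
            raise ValueError(
                f"unknown residue {aa!r} at position {i + 1} (1-based); "
                "only the 20 standard one-letter codes are supported"
            )


def peptide_mass(seq: str, kind: str = "monoisotopic", charge_state: str = "neutral") -> float:
    """Mass of a peptide from standard residue mass tables.

    Parameters
    ----------
    seq : str
        Residues in one-letter code (20 standard amino acids).
    kind : {"monoisotopic", "average"}
        Isotope convention for the residue masses.
    charge_state : {"neutral", "MH+"}
        ``"neutral"`` returns the uncharged molecular mass M (residues +
        water); ``"MH+"`` adds one proton, the m/z of the singly protonated
        ion as printed for linear-TOF peaks.
    """
    _validate_sequence(seq)
    if kind not in ("monoisotopic", "average"):
        raise ValueError(f"kind must be 'monoisotopic' or 'average', got {kind!r}")
    if charge_state not in ("neutral", "MH+"):
        raise ValueError(f"charge_state must be 'neutral' or 'MH+', got {charge_state!r}")
    m = _ptmass.calculate_mass(sequence=seq, average=(kind == "average"))
    if charge_state == "MH+":
        m += _ptmass.nist_mass["H+"][0][0]
    return m


@dataclass(frozen=True)
class FragmentDescriptor:
    """A contiguous fragment of a parent protein in 1-based inclusive coordinates."""

    parent_length: int
    start: int
    end: int
    length: int
    #: True when the residue after the gap position is the start of a declared
    #: downstream subunit, i.e. the fragment stops exactly one residue short
    #: of a known processing boundary.
    abuts_known_subunit: bool
    #: 1-based position of the single residue between fragment end and the
    #: subunit start (None when the fragment does not abut a subunit).
    missing_residue_position: int | None


def map_fragment(
    parent_length: int,
    start: int,
    end: int,
    subunit_start: int | None = None,
) -> FragmentDescriptor:
    """Describe a fragment of a parent chain and flag subunit adjacency.

    ``subunit_start`` is the 1-based first residue of a known downstream
    subunit; when ``end + 2 == subunit_start`` the fragment abuts it with a
    single missing residue in between (position ``end + 1``).
    """
    if not (1 <= start <= end <= parent_length):
        raise ValueError(
            f"invalid fragment coordinates ({start}, {end}) for parent of "
            f"length {parent_length}; need 1 <= start <= end <= parent_length"
        )
    abuts = subunit_start is not None and end + 2 == subunit_start
    return FragmentDescriptor(
        parent_length=parent_length,
        start=start,
        end=end,
        length=end - start + 1,
        abuts_known_subunit=abuts,
        missing_residue_position=end + 1 if abuts else None,
    )
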