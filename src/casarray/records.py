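"""Core record types for Cas12a crRNA arrays.

A Cas12a crRNA array is a single transcript of alternating 19-nt direct
repeats (DRs) and 19-23 nt spacers.  Using a distinct DR variant at each
array position suppresses recombination between repeated sequences during
lentiviral delivery, and the position-specific DR sequences double as exact
anchors when mapping sequencing reads back to constructs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "DNA_ALPHABET",
    "revcomp",
    "validate_dna",
    "Spacer",
    "SPACER_CATEGORIES",
    "TARGETING_CATEGORIES",
    "DirectRepeat",
    "DR_SEQUENCES",
    "DR_ASSIGNMENTS",
    "DirectRepeatAssignment",
    "ArrayConstruct",
    "ConstructLibrary",
]

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, who: str = "sequence") -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"{who} contains non-DNA characters {sorted(bad)}: {seq!r}"
        )


SPACER_CATEGORIES = frozenset(
    {
        "tss_targeting",
        "enhancer_targeting",
        "promoter_targeting",
        "intergenic_negative",
        "nontargeting_negative",
    }
)

#: Categories for which a target label is mandatory.
TARGETING_CATEGORIES = frozenset(
    {"tss_targeting", "enhancer_targeting", "promoter_targeting"}
)

#: Sentinel used by guide-design off-target annotations.
OFFTARGET_MAX = "MAX"


@dataclass(frozen=True)
class Spacer:
    """A 19-23 nt Cas12a targeting sequence with design annotations.

    Annotation fields mirror the columns of CRISPick-style candidate
    tables; absent annotations are ``None`` (numeric) or ``""`` (text).
    """

    id: str
    sequence: str
    category: str = "tss_targeting"
    target_id: str = ""
    pam: str = ""
    pam_class: str = "canonical_TTTV"
    tss_offset: Optional[int] = None
    on_target_efficacy: Optional[float] = None
    offtarget_match_flag: str = ""
    tier1_bin1_matches: Optional[int] = None

    def validate(self) -> None:
        validate_dna(self.sequence, who=f"spacer {self.id!r}")
        n = len(self.sequence)
        if not 19 <= n <= 23:
            raise ValueError(
                f"spacer {self.id!r} has length {n}; must be 19-23 nt"
            )
        if self.category not in SPACER_CATEGORIES:
            raise ValueError(
                f"spacer {self.id!r} has unknown category {self.category!r}"
            )
        if self.category in TARGETING_CATEGORIES and not self.target_id:
            raise ValueError(
                f"targeting spacer {self.id!r} requires a target_id"
            )
        if self.on_target_efficacy is not None and not (
            0.0 <= self.on_target_efficacy <= 1.0
        ):
            raise ValueError(
                f"spacer {self.id!r}: on_target_efficacy outside [0, 1]"
            )
        if self.tier1_bin1_matches is not None and self.tier1_bin1_matches < 0:
            raise ValueError(
                f"spacer {self.id!r}: tier1_bin1_matches must be >= 0"
            )


@dataclass(frozen=True)
class DirectRepeat:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        validate_dna(self.sequence, who=f"direct repeat {self.name!r}")
        if len(self.sequence) != 19:
            raise ValueError(
                f"direct repeat {self.name!r} must be 19 nt, "
                f"got {len(self.sequence)}"
            )


#: Direct-repeat variant sequences (all 19 nt).  WT is the natural
#: AsCas12a repeat; numbered and NS variants were selected to minimise
#: homology across array positions while retaining processing activity.
DR_SEQUENCES: Mapping[str, str] = {
    "WT": "AATTTCTACTCTTGTAGAT",
    "DR1": "AATTTCTACTGTCGTAGAT",
    "DR16": "AATTCCTACTATTGTAGGT",
    "DR_NS1": "AATTCCTCCTCTTGGAGGT",
    "DR4": "AATTTCTACTATTGTAGAT",
    "DR_NS2": "AATTCCTCCTATAGGAGGT",
    "DR17": "AATTTCTCCTATAGGAGAT",
    "DR18": "AATTCCTACTCTAGTAGGT",
    "DR10": "AATTCCTACTCTCGTAGGT",
    "DR3": "AATTTCTACTCTAGTAGAT",
    "DR8": "AATTTCTCCTCTAGGAGAT",
}

#: Position assignments of DR variants per plex level, 5'->3'.  Every
#: assignment starts with the WT repeat (fixed in the expression vector)
#: and ends with DR8 (the vector's terminal repeat variant).  Single-plex
#: constructs in the DR8 vector are WT + spacer + DR8.
DR_ASSIGNMENTS: Mapping[int, tuple[str, ...]] = {
    1: ("WT", "DR8"),
    3: ("WT", "DR1", "DR3", "DR8"),
    4: ("WT", "DR1", "DR10", "DR3", "DR8"),
    5: ("WT", "DR1", "DR16", "DR10", "DR3", "DR8"),
    6: ("WT", "DR1", "DR16", "DR18", "DR10", "DR3", "DR8"),
    8: ("WT", "DR1", "DR16", "DR_NS1", "DR17", "DR18", "DR10", "DR3", "DR8"),
    10: (
        "WT",
        "DR1",
        "DR16",
        "DR_NS1",
        "DR4",
        "DR_NS2",
        "DR17",
        "DR18",
        "DR10",
        "DR3",
        "DR8",
    ),
}


def direct_repeat(name: str) -> DirectRepeat:
    try:
        return DirectRepeat(name, DR_SEQUENCES[name])
    except KeyError:
        raise KeyError(
            f"unknown direct repeat {name!r}; known: {sorted(DR_SEQUENCES)}"
        ) from None


@dataclass(frozen=True)
class DirectRepeatAssignment:
    """Ordered DR variants flanking each spacer of a plex-N array."""

    plex: int
    ordered_drs: tuple[DirectRepeat, ...]

    def __post_init__(self) -> None:
        if self.plex < 1:
            raise ValueError("plex must be >= 1")
        if len(self.ordered_drs) != self.plex + 1:
            raise ValueError(
                f"{self.plex}-plex assignment needs {self.plex + 1} DRs, "
                f"got {len(self.ordered_drs)}"
            )
        names = [dr.name for dr in self.ordered_drs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate DR names in assignment: {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(dr.name for dr in self.ordered_drs)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(dr.sequence for dr in self.ordered_drs)


@dataclass(frozen=True)
class ArrayConstruct:
    """An assembled crRNA array: DR0 + s1 + DR1 + ... + sN + DRN."""

    id: str
    spacers: tuple[Spacer, ...]
    dr_assignment: DirectRepeatAssignment
    sequence: str
    test_position: Optional[int] = None
    context_set_id: Optional[str] = None

    @property
    def plex(self) -> int:
        return len(self.spacers)

    @property
    def spacer_tuple(self) -> tuple[str, ...]:
        return tuple(s.sequence for s in self.spacers)

    @property
    def spacer_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.spacers)


class ConstructLibrary:
    """A set of array constructs indexed by their ordered spacer tuple.

    Construct ids are unique and no two constructs may share a spacer
    tuple, so the tuple index is a bijection onto the constructs.
    """

    def __init__(self, constructs: Iterable[ArrayConstruct] = ()) -> None:
        self._by_id: dict[str, ArrayConstruct] = {}
        self._by_tuple: dict[tuple[str, ...], str] = {}
        for c in constructs:
            self.add(c)

    def add(self, construct: ArrayConstruct) -> None:
        if construct.id in self._by_id:
            raise ValueError(f"duplicate construct id {construct.id!r}")
        key = construct.spacer_tuple
        if key in self._by_tuple:
            raise ValueError(
                f"constructs {self._by_tuple[key]!r} and {construct.id!r} "
                "share an identical spacer tuple"
            )
        self._by_id[construct.id] = construct
        self._by_tuple[key] = construct.id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def __contains__(self, construct_id: str) -> bool:
        return construct_id in self._by_id

    def __getitem__(self, construct_id: str) -> ArrayConstruct:
        return self._by_id[construct_id]

    @property
    def index(self) -> Mapping[tuple[str, ...], str]:
        return dict(self._by_tuple)

    @property
    def plex_levels(self) -> set[int]:
        return {c.plex for c in self}

    def lookup(self, spacer_tuple: tuple[str, ...]) -> Optional[str]:
        return self._by_tuple.get(tuple(spacer_tuple))

    def ids(self) -> list[str]:
        return list(self._by_id)
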