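"""Sequence-level model of dCas9 guide-target recognition.

A catalytically dead Cas9 (dCas9) ribonucleoprotein engages a 20-bp double
stranded DNA target only when an NGG protospacer-adjacent motif (PAM) sits
next to it; the crRNA spacer then hybridizes to the target starting from the
PAM-proximal end.  Mismatches between spacer and protospacer in the
PAM-proximal "seed" region (first ~8-12 nt) largely abolish stable binding,
while PAM-distal mismatches are tolerated to varying degree; certain
non-Watson-Crick RNA-DNA pairings (rG-dT, rU-dG, rA-dC, rC-dA, the "wobble"
pairs) are systematically better tolerated than other mispairs.

This module provides the bookkeeping for that biology: PAM scanning, a
position-resolved mismatch profile between a guide and a target site, wobble
classification, and a configurable multiplicative binding-probability model
used to parameterize trace simulations.  The multiplier table is user
configuration, not measured truth: per-guide mismatch tolerance varies too
much between guides for a universal table to exist.

Position convention (used everywhere in this package): position 1 is the
PAM-proximal base of the spacer/protospacer, increasing toward the PAM-distal
end; string index 0 of the stored sequences corresponds to position 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import yaml

__all__ = [
    "ConfigurationError",
    "GuideProbe",
    "TargetSite",
    "MismatchEntry",
    "MismatchProfile",
    "BindingModelParams",
    "find_pam_sites",
    "mismatch_profile",
    "is_wobble_pair",
    "binding_probability",
    "rna_transcript",
    "default_binding_params",
]

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")
SPACER_LENGTH = 20

#: RNA transcript equivalent of each DNA base (identity of the protospacer
#: strand with T -> U); a spacer position "matches" its protospacer position
#: when the spacer base equals this transcript equivalent.
_RNA_OF_DNA = {"A": "A", "C": "C", "G": "G", "T": "U"}

#: Tolerated non-Watson-Crick guide(RNA)-target(DNA) pairings, written as
#: (guide base, DNA base it faces): rG-dT, rU-dG, rA-dC, rC-dA.
WOBBLE_PAIRS = frozenset({("G", "T"), ("U", "G"), ("A", "C"), ("C", "A")})


class ConfigurationError(ValueError):
    """A user-supplied parameter table or config is incomplete or invalid."""


def _check_alphabet(seq: str, alphabet: frozenset, what: str) -> None:
    for ch in seq:
        if ch not in alphabet:
            raise ValueError(
                f"invalid character {ch!r} in {what}: expected one of "
                f"{''.join(sorted(alphabet))}"
            )


def rna_transcript(dna: str) -> str:
    """Return the RNA transcript equivalent of a DNA string (T -> U)."""
    _check_alphabet(dna, DNA_ALPHABET, "DNA sequence")
    return dna.replace("T", "U")


@dataclass(frozen=True)
class GuideProbe:
    """A crRNA probe, identified by its 20-nt spacer.

    ``spacer[0]`` is the PAM-proximal base (position 1).
    """

    name: str
    spacer: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacer", self.spacer.upper())
        if len(self.spacer) != SPACER_LENGTH:
            raise ValueError(
                f"spacer must be {SPACER_LENGTH} nt, got {len(self.spacer)}"
            )
        _check_alphabet(self.spacer, RNA_ALPHABET, "spacer")


@dataclass(frozen=True)
class TargetSite:
    """A 20-bp protospacer with its adjacent 3-nt PAM.

    ``protospacer[0]`` is the PAM-proximal base (position 1).
    """

    protospacer: str
    pam: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        object.__setattr__(self, "pam", self.pam.upper())
        if len(self.protospacer) != SPACER_LENGTH:
            raise ValueError(
                f"protospacer must be {SPACER_LENGTH} nt, got {len(self.protospacer)}"
            )
        if len(self.pam) != 3:
            raise ValueError(f"pam must be 3 nt, got {len(self.pam)}")
        _check_alphabet(self.protospacer, DNA_ALPHABET, "protospacer")
        _check_alphabet(self.pam, DNA_ALPHABET, "pam")

    @property
    def has_valid_pam(self) -> bool:
        """True iff the PAM matches N-G-G."""
        return self.pam[1] == "G" and self.pam[2] == "G"


@dataclass(frozen=True)
class MismatchEntry:
    position: int  # 1-based, counted from the PAM-proximal end
    rna_base: str
    dna_base: str
    is_wobble: bool


@dataclass(frozen=True)
class MismatchProfile:
    """Positions at which a guide and a target site disagree."""

    entries: Tuple[MismatchEntry, ...]
    seed_boundary: int = 12

    def __post_init__(self) -> None:
        positions = [e.position for e in self.entries]
        if any(not (1 <= p <= SPACER_LENGTH) for p in positions):
            raise ValueError("mismatch positions must lie in [1, 20]")
        if any(b >= a for a, b in zip(positions[1:], positions)):
            raise ValueError("mismatch positions must be strictly increasing")
        for e in self.entries:
            if e.is_wobble != is_wobble_pair(e.rna_base, e.dna_base):
                raise ValueError(
                    f"inconsistent wobble flag for {e.rna_base}-{e.dna_base} "
                    f"at position {e.position}"
                )

    @property
    def n_mismatches(self) -> int:
        return len(self.entries)

    def seed_mismatches(self) -> Tuple[MismatchEntry, ...]:
        """Entries inside the PAM-proximal seed region."""
        return tuple(e for e in self.entries if e.position <= self.seed_boundary)


@dataclass(frozen=True)
class BindingModelParams:
    """Multiplicative binding-probability model.

    A perfectly matched target with a valid PAM binds with probability
    ``baseline_efficiency`` (default 0.337, the control binding efficiency
    of a matched probe under high-salt nanopore conditions).  Each mismatch
    at position ``p`` multiplies that probability by
    ``per_position_ratio[(p, is_wobble)]``; a target without a valid PAM
    binds with ``no_pam_probability`` regardless of sequence.  The default
    per-position ratios are illustrative band values (seed non-wobble 0.1,
    seed wobble 0.6, distal 0.9), not measured constants.
    """

    baseline_efficiency: float = 0.337
    per_position_ratio: Mapping[Tuple[int, bool], float] = field(default=None)
    no_pam_probability: float = 0.0
    seed_boundary: int = 12

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_efficiency <= 1.0:
            raise ValueError("baseline_efficiency must lie in [0, 1]")
        if not 0.0 <= self.no_pam_probability <= 1.0:
            raise ValueError("no_pam_probability must lie in [0, 1]")
        if self.per_position_ratio is None:
            object.__setattr__(
                self,
                "per_position_ratio",
                _band_table(0.1, 0.6, 0.9, 0.9, self.seed_boundary),
            )
        for key, ratio in self.per_position_ratio.items():
            if ratio < 0:
                raise ValueError(f"multiplier for {key} must be >= 0")

    @classmethod
    def from_bands(
        cls,
        seed_non_wobble: float,
        seed_wobble: float,
        distal_non_wobble: float,
        distal_wobble: float,
        baseline_efficiency: float = 0.337,
        no_pam_probability: float = 0.0,
        seed_boundary: int = 12,
    ) -> "BindingModelParams":
        """Expand seed/distal band multipliers into a full per-position table."""
        return cls(
            baseline_efficiency=baseline_efficiency,
            per_position_ratio=_band_table(
                seed_non_wobble, seed_wobble, distal_non_wobble, distal_wobble,
                seed_boundary,
            ),
            no_pam_probability=no_pam_probability,
            seed_boundary=seed_boundary,
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "BindingModelParams":
        d = dict(d)
        bands = d.pop("band_ratios", None)
        unknown = set(d) - {
            "baseline_efficiency", "no_pam_probability", "seed_boundary",
            "per_position_ratio",
        }
        if unknown:
            raise ConfigurationError(f"unknown binding-model keys: {sorted(unknown)}")
        if bands is not None:
            return cls.from_bands(
                seed_non_wobble=bands["seed"]["non_wobble"],
                seed_wobble=bands["seed"]["wobble"],
                distal_non_wobble=bands["distal"]["non_wobble"],
                distal_wobble=bands["distal"]["wobble"],
                **d,
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "BindingModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _band_table(
    seed_non_wobble: float,
    seed_wobble: float,
    distal_non_wobble: float,
    distal_wobble: float,
    seed_boundary: int,
) -> Dict[Tuple[int, bool], float]:
    table: Dict[Tuple[int, bool], float] = {}
    for pos in range(1, SPACER_LENGTH + 1):
        in_seed = pos <= seed_boundary
        table[(pos, False)] = seed_non_wobble if in_seed else distal_non_wobble
        table[(pos, True)] = seed_wobble if in_seed else distal_wobble
    return table


def default_binding_params() -> BindingModelParams:
    """Load the packaged illustrative default multiplier table."""
    from importlib.resources import files

    path = files("caspore.data").joinpath("binding_defaults.yaml")
    return BindingModelParams.from_dict(yaml.safe_load(path.read_text()))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def find_pam_sites(dna_sequence: str) -> List[int]:
    """Return all 0-based offsets of NGG motifs on the given strand, 5'->3'.

    Overlapping matches are all reported; the reverse complement is not
    scanned (overhang constructs are short, oriented sequences).
    """
    seq = dna_sequence.upper()
    _check_alphabet(seq, DNA_ALPHABET, "DNA sequence")
    if len(seq) < 3:
        raise ValueError("sequence must be at least 3 nt to contain a PAM")
    return [i for i in range(len(seq) - 2) if seq[i + 1] == "G" and seq[i + 2] == "G"]


def is_wobble_pair(rna_base: str, dna_base: str) -> bool:
    """True for the tolerated wobble pairings rG-dT, rU-dG, rA-dC, rC-dA.

    The pair denotes the guide base opposite the target-strand DNA base it
    faces; Watson-Crick matches are not wobble.
    """
    if rna_base not in RNA_ALPHABET:
        raise ValueError(f"invalid RNA base {rna_base!r}")
    if dna_base not in DNA_ALPHABET:
        raise ValueError(f"invalid DNA base {dna_base!r}")
    return (rna_base, dna_base) in WOBBLE_PAIRS


def mismatch_profile(
    probe: GuideProbe, site: TargetSite, seed_boundary: int = 12
) -> MismatchProfile:
    """Profile spacer/protospacer disagreements, PAM-proximal position 1 first.

    Position ``p`` matches when the spacer base equals the RNA transcript
    equivalent of the protospacer base (A-A, C-C, G-G, U-T); every other
    combination is recorded with its wobble classification.
    """
    entries = []
    for idx, (r, d) in enumerate(zip(probe.spacer, site.protospacer)):
        if r != _RNA_OF_DNA[d]:
            entries.append(
                MismatchEntry(
                    position=idx + 1,
                    rna_base=r,
                    dna_base=d,
                    is_wobble=is_wobble_pair(r, d),
                )
            )
    return MismatchProfile(entries=tuple(entries), seed_boundary=seed_boundary)


def binding_probability(
    profile: MismatchProfile,
    site: TargetSite,
    params: Optional[BindingModelParams] = None,
) -> float:
    """Probability that the dCas9 RNP stably binds the given site.

    No valid PAM short-circuits to ``params.no_pam_probability``; otherwise
    the baseline efficiency is multiplied by the configured ratio for every
    mismatch and the result clamped to [0, 1].  A mismatch with no configured
    multiplier raises :class:`ConfigurationError` rather than assuming one.
    """
    if params is None:
        params = BindingModelParams()
    if not site.has_valid_pam:
        return params.no_pam_probability
    p = params.baseline_efficiency
    for entry in profile.entries:
        key = (entry.position, entry.is_wobble)
        if key not in params.per_position_ratio:
            raise ConfigurationError(
                f"no binding multiplier configured for position {entry.position} "
                f"(wobble={entry.is_wobble})"
            )
        p *= params.per_position_ratio[key]
    return min(max(p, 0.0), 1.0)


def matched_probe(name: str, site: TargetSite) -> GuideProbe:
    """Convenience: the probe whose spacer perfectly matches ``site``."""
    return GuideProbe(name=name, spacer=rna_transcript(site.protospacer))
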