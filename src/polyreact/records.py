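"""Core record types: antibody chains, extracted variable domains, assay points.

An antibody is held as up to four chains (HC1, LC1, HC2, LC2); after
canonicalization each occupied slot carries a unique sequence.  Variable
domains extracted from those chains fill up to four slots (var1..var4)
together with a length-4 location vector coding the chain of origin
(0 = slot empty, 1 = HC1, 2 = LC1, 3 = HC2, 4 = LC2).

The unit of modelling is the :class:`AssayPoint`: one antibody measured at
one concentration on one well coating, with its ELISA fold-over-control
readout and the binary polyreactivity label derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import UnsupportedFormatError, ValidationError
from .residues import is_valid_sequence

CHAIN_SLOTS: tuple[str, ...] = ("hc1", "lc1", "hc2", "lc2")

#: location code for a domain extracted from each chain slot
CHAIN_LOCATION_CODE: dict[str, int] = {"hc1": 1, "lc1": 2, "hc2": 3, "lc2": 4}

MAX_CHAIN_LENGTH = 10_000

MONOSPECIFIC_FORMATS = frozenset({"canonical", "vhh_fc"})


@dataclass(frozen=True)
class AntibodyRecord:
    """Raw (or canonicalized) chain set of one antibody."""

    id: str
    hc1: str
    lc1: Optional[str] = None
    hc2: Optional[str] = None
    lc2: Optional[str] = None
    format_label: str = "unknown"

    def chains(self) -> dict[str, Optional[str]]:
        return {slot: getattr(self, slot) for slot in CHAIN_SLOTS}

    def sequence_key(self) -> tuple:
        """Hashable identity of the molecule: the multiset of its chains."""
        return tuple(getattr(self, slot) for slot in CHAIN_SLOTS)

    def is_bispecific(self) -> bool:
        return self.format_label.startswith("bispecific")

    def validate(self) -> "AntibodyRecord":
        if not self.hc1:
            raise ValidationError(f"record {self.id!r}: hc1 must be non-null")
        for slot, seq in self.chains().items():
            if seq is None:
                continue
            if not is_valid_sequence(seq):
                bad = sorted({c for c in seq if c not in "ACDEFGHIKLMNPQRSTVWY"})
                raise ValidationError(
                    f"record {self.id!r}: chain {slot} contains non-amino-acid "
                    f"characters {bad}"
                )
            if len(seq) > MAX_CHAIN_LENGTH:
                raise ValidationError(
                    f"record {self.id!r}: chain {slot} longer than "
                    f"{MAX_CHAIN_LENGTH} residues"
                )
        if self.hc2 is not None and self.hc2 == self.hc1:
            raise ValidationError(
                f"record {self.id!r}: hc2 duplicates hc1; canonicalize first"
            )
        return self


def canonicalize_chains(record: AntibodyRecord) -> AntibodyRecord:
    """Collapse duplicate chains into unique slots (stoichiometry-aware).

    A canonical IgG supplied with two identical heavy and two identical light
    chains reduces to (HC1, LC1, -, -); a knob-into-hole molecule with a
    common light chain keeps both distinct heavy chains as HC1/HC2; a VHH-Fc
    homodimer keeps only HC1.  Idempotent.
    """
    heavies = _unique_in_order([record.hc1, record.hc2])
    lights = _unique_in_order([record.lc1, record.lc2])
    if not heavies:
        raise UnsupportedFormatError(f"record {record.id!r}: no heavy chain")
    if len(heavies) > 2 or len(lights) > 2:
        raise UnsupportedFormatError(
            f"record {record.id!r}: more than two distinct heavy or light chains"
        )
    slots = {
        "hc1": heavies[0],
        "hc2": heavies[1] if len(heavies) > 1 else None,
        "lc1": lights[0] if lights else None,
        "lc2": lights[1] if len(lights) > 1 else None,
    }
    return replace(record, **slots).validate()


def _unique_in_order(seqs) -> list[str]:
    seen: list[str] = []
    for s in seqs:
        if s and s not in seen:
            seen.append(s)
    return seen


@dataclass(frozen=True)
class VariableDomainSet:
    """Up to four extracted variable domains with their chain-of-origin codes.

    ``per_chain_groups`` maps each contributing chain slot to the ordered
    (N- to C-terminal) list of var-slot indices (1-based) it carries; this
    within-chain adjacency is what the G4S concatenation scheme consumes.
    """

    var1: str
    var2: Optional[str] = None
    var3: Optional[str] = None
    var4: Optional[str] = None
    location: tuple[int, int, int, int] = (1, 0, 0, 0)
    per_chain_groups: dict = field(default_factory=dict)

    MIN_DOMAIN_LEN = 60

    def domains(self) -> tuple[Optional[str], ...]:
        return (self.var1, self.var2, self.var3, self.var4)

    def n_domains(self) -> int:
        return sum(d is not None for d in self.domains())

    def hc_only(self) -> bool:
        """True when every domain comes from a heavy chain."""
        return all(code in (0, 1, 3) for code in self.location)

    def validate(self, capacity: int = 132) -> "VariableDomainSet":
        if not self.var1:
            raise ValidationError("var1 must be non-null")
        if len(self.location) != 4:
            raise ValidationError("location vector must have length 4")
        for i, (dom, code) in enumerate(zip(self.domains(), self.location), 1):
            if (dom is None) != (code == 0):
                raise ValidationError(
                    f"location[{i - 1}]={code} inconsistent with var{i} nullity"
                )
            if code not in (0, 1, 2, 3, 4):
                raise ValidationError(f"location code {code} out of range 0..4")
            if dom is not None and not (
                self.MIN_DOMAIN_LEN <= len(dom) <= capacity
            ):
                raise ValidationError(
                    f"var{i} length {len(dom)} outside "
                    f"[{self.MIN_DOMAIN_LEN}, {capacity}]"
                )
        return self

    def to_json_dict(self) -> dict:
        return {
            "var1": self.var1,
            "var2": self.var2,
            "var3": self.var3,
            "var4": self.var4,
            "location": list(self.location),
            "per_chain_groups": {k: list(v) for k, v in self.per_chain_groups.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "VariableDomainSet":
        return cls(
            var1=d["var1"],
            var2=d.get("var2"),
            var3=d.get("var3"),
            var4=d.get("var4"),
            location=tuple(d["location"]),
            per_chain_groups={k: list(v) for k, v in d.get("per_chain_groups", {}).items()},
        )


@dataclass(frozen=True)
class AssayPoint:
    """One unique data point: (antibody, concentration, coating) + readout."""

    antibody: AntibodyRecord
    concentration_nM: float
    coating: str  # "BVP" or "BSA"
    fold_over_control: float
    label: int

    def uniqueness_key(self) -> tuple:
        return (
            self.antibody.sequence_key(),
            round(float(self.concentration_nM), 6),
            self.coating,
        )
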