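"""Variable-domain localisation on antibody chains.

The production path of this kind of pipeline would call an external
antibody-numbering tool (ANARCI / abnumber); those are exposed here as an
optional adapter.  The default backend is a dependency-free scanner that
anchors on features invariant across immunoglobulin V domains:

* the first framework cysteine, 22nd (heavy) or 23rd (light/kappa) residue
  of the domain,
* the second framework cysteine closing the CDR3 loop, and
* the J-segment motif [W/F]-G-x-G-T that opens framework 4.

A heavy-type domain (FR4 starting with W) spans 11 FR4 residues, a
kappa-type domain (FR4 starting with F) spans 10.  The scanner walks a chain
N- to C-terminal, emitting non-overlapping domains; intervening linkers or
constant-region segments are skipped.  It is validated against the synthetic
generator's ground-truth boundary annotations, not against an external
numbering scheme.
"""

from __future__ import annotations

import re
from typing import Optional, Protocol

from .errors import DependencyError, ExtractionError, UnsupportedFormatError
from .records import (
    CHAIN_LOCATION_CODE,
    CHAIN_SLOTS,
    AntibodyRecord,
    VariableDomainSet,
)

J_MOTIF = re.compile(r"[WF]G.GT")

#: FR4 length by J-motif first letter
_FR4_LEN = {"W": 11, "F": 10}
#: offset of the first framework Cys from the domain start
_FR1_CYS_OFFSET = {"W": 21, "F": 22}

MAX_DOMAINS = 4


class NumberingBackend(Protocol):
    """Anything that can locate variable domains on a single chain."""

    def find_domains(self, chain: str) -> list[tuple[int, int]]:
        """Return [(start, end), ...] half-open intervals, N- to C-terminal."""
        ...


class MotifAnchorScanner:
    """Built-in conserved-motif domain finder (see module docstring)."""

    #: window (relative to the J motif) searched for the CDR3-closing Cys
    CDR3_CYS_WINDOW = (3, 45)
    #: window (relative to the CDR3 Cys) searched for the FR1 Cys
    FR1_CYS_WINDOW = (50, 80)
    MIN_LEN, MAX_LEN = 60, 150

    def find_domains(self, chain: str) -> list[tuple[int, int]]:
        domains: list[tuple[int, int]] = []
        cursor = 0
        for m in J_MOTIF.finditer(chain):
            j = m.start()
            if j < cursor:
                continue  # motif inside an already-claimed domain
            kind = chain[j]
            end = min(j + _FR4_LEN[kind], len(chain))
            lo, hi = self.CDR3_CYS_WINDOW
            cdr3_cys = chain.rfind("C", max(cursor, j - hi), j - lo + 1)
            if cdr3_cys < 0:
                continue
            lo, hi = self.FR1_CYS_WINDOW
            fr1_cys = chain.rfind("C", max(cursor, cdr3_cys - hi), cdr3_cys - lo + 1)
            if fr1_cys < 0:
                continue
            start = fr1_cys - _FR1_CYS_OFFSET[kind]
            if start < cursor:
                continue
            if not (self.MIN_LEN <= end - start <= self.MAX_LEN):
                continue
            domains.append((start, end))
            cursor = end
        return domains


class AnnotationBackend:
    """Backend replaying generator-recorded ground-truth boundaries.

    Used in tests to decouple downstream stages from the scanner.
    """

    def __init__(self, boundaries_by_chain: dict[str, list[tuple[int, int]]]):
        self._by_chain = boundaries_by_chain

    def find_domains(self, chain: str) -> list[tuple[int, int]]:
        return [tuple(b) for b in self._by_chain.get(chain, [])]


class AnarciAdapter:
    """Adapter delegating to the external `anarci` package (optional)."""

    def __init__(self) -> None:
        try:
            import anarci  # noqa: F401
        except ImportError as exc:  # pragma: no cover - external tool
            raise DependencyError(
                "the anarci package is not installed; use the default "
                "MotifAnchorScanner or install anarci"
            ) from exc
        self._anarci = anarci

    def find_domains(self, chain: str) -> list[tuple[int, int]]:  # pragma: no cover
        numbered, details, _ = self._anarci.anarci(
            [("chain", chain)], scheme="imgt", output=False
        )
        out = []
        if numbered and numbered[0]:
            for dom, det in zip(numbered[0], details[0]):
                out.append((det["query_start"], det["query_end"] + 1))
        return sorted(out)


def extract_variable_domains(
    record: AntibodyRecord,
    backend: Optional[NumberingBackend] = None,
    capacity: int = 132,
) -> VariableDomainSet:
    """Extract up to four variable domains from a canonicalized record.

    Domains are assigned to var slots chain-major (HC1, LC1, HC2, LC2), then
    N- to C-terminal within a chain; the location vector records the chain of
    origin of each slot (1..4, 0 for empty).
    """
    backend = backend or MotifAnchorScanner()
    seqs: list[str] = []
    codes: list[int] = []
    groups: dict[str, list[int]] = {}
    for slot in CHAIN_SLOTS:
        chain = getattr(record, slot)
        if chain is None:
            continue
        found = backend.find_domains(chain)
        slot_indices = []
        for start, end in found:
            if len(seqs) >= MAX_DOMAINS:
                raise UnsupportedFormatError(
                    f"record {record.id!r}: more than {MAX_DOMAINS} variable "
                    "domains; unsupported layout"
                )
            seqs.append(chain[start:end])
            codes.append(CHAIN_LOCATION_CODE[slot])
            slot_indices.append(len(seqs))
        if slot_indices:
            groups[slot] = slot_indices
    if not seqs:
        raise ExtractionError(
            f"record {record.id!r}: no variable domain found on any chain"
        )
    padded = seqs + [None] * (MAX_DOMAINS - len(seqs))
    location = tuple(codes + [0] * (MAX_DOMAINS - len(codes)))
    return VariableDomainSet(
        var1=padded[0],
        var2=padded[1],
        var3=padded[2],
        var4=padded[3],
        location=location,
        per_chain_groups=groups,
    ).validate(capacity=capacity)
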