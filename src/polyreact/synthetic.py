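"""Synthetic antibody panels with a known polyreactivity mechanism.

The generator emulates the structure of a discovery-stage ELISA screening
campaign: a panel mixing canonical IgGs, VHH-Fcs and several bispecific
layouts, each molecule measured at one or more concentrations on BVP- and
BSA-coated wells, with a fold-over-control readout.

Sequences are built from fixed human-like V-domain scaffolds whose framework
regions carry the invariant cysteines and J-segment [W/F]GxGT motif that the
built-in domain scanner anchors on; CDR-like windows are randomized per
antibody with a bias controlled by two latent traits (charge, hydrophobicity)
drawn per molecule.  Spacer segments (G4S linkers, constant-region and Fc
stubs) are synthetic and deliberately free of cysteines and J-like motifs so
that domain boundaries are unambiguous.

The ground-truth readout rule: each molecule's positive-charge load ``q``
(clipped sum of per-domain net charge at pH 7.4) and hydrophobic load ``h``
(clipped mean of per-domain CDR hydropathy) combine into a coating-specific
binding propensity

    propensity = a_coat_charge * w_charge * q + a_coat_hydro * w_hydro * h

and the fold over control at concentration ``c`` is

    fold = 1 + propensity * (c / 667)**gamma * eps,   eps ~ lognormal(0, sigma)

so polyreactivity (fold > 2) is concentration-dependent: weak binders flip
to clean at the lower concentration.  BSA is dominated by charge (BSA is
negatively charged at assay pH), BVP responds to both hydrophobicity and
charge.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ValidationError
from .featurize import encode_label
from .numbering import MotifAnchorScanner
from .records import AntibodyRecord, AssayPoint
from .residues import CHARGE_PH74, KYTE_DOOLITTLE

# ---------------------------------------------------------------------------
# scaffolds

#: framework regions (FR1, FR2, FR3, FR4) of the three domain scaffolds
FRAMEWORKS: dict[str, tuple[str, str, str, str]] = {
    "VH": (
        "EVQLLESGGGLVQPGGSLRLSCAAS",
        "WVRQAPGKGLEWVS",
        "RFTISRDNSKNTLYLQMNSLRAEDTAVYYC",
        "WGQGTLVTVSS",
    ),
    "VL": (
        "DIQMTQSPSSLSASVGDRVTITC",
        "WYQQKPGKAPKLLIY",
        "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC",
        "FGQGTKVEIK",
    ),
    "VHH": (
        "QVQLVESGGGLVQAGGSLRLSCAAS",
        "WVRQAPGKERELVA",
        "RFTISRDNAKNTVYLQMNSLKPEDTAVYYC",
        "WGQGTQVTVSS",
    ),
}

#: (CDR1 len, CDR2 len, CDR3 len range) per scaffold
CDR_LENGTHS: dict[str, tuple[int, int, tuple[int, int]]] = {
    "VH": (8, 8, (8, 16)),
    "VL": (11, 7, (8, 10)),
    "VHH": (8, 8, (10, 16)),
}

# Synthetic spacers: no Cys, no Trp/Phe (hence no J-like motif can form).
G4S_LINKER3 = "GGGGSGGGGSGGGGS"
CH1_STUB = "ASTKGPSVLPLAPSSKSTSGGTAALG"
HINGE_FC_STUB = "EPKSSDKTHTSPPSPAPELLGGPSVLLPPKPKDTLMISRTPEVT"
CL_STUB = "RTVAAPSVLIPPSDEQLKSGTASVVLLLNNVYPREAKVQ"

#: CDR sampling alphabet: the 20 standard residues minus cysteine
CDR_ALPHABET = "ADEFGHIKLMNPQRSTVWY"

_CDR_CHARGE = np.array([CHARGE_PH74[a] for a in CDR_ALPHABET])
_CDR_KD = np.array([KYTE_DOOLITTLE[a] for a in CDR_ALPHABET])

#: format name -> (scaffold kinds per chain slot); each chain slot lists the
#: domains it carries in N->C order
FORMAT_LAYOUTS: dict[str, dict[str, list[str]]] = {
    "canonical": {"hc1": ["VH"], "lc1": ["VL"]},
    "vhh_fc": {"hc1": ["VHH"]},
    "scfv_ig": {"hc1": ["VH", "VH"], "lc1": ["VL"]},
    "dvd": {"hc1": ["VH", "VH"], "lc1": ["VL", "VL"]},
    "kih_common_lc": {"hc1": ["VH"], "lc1": ["VL"], "hc2": ["VH"]},
    "bispecific_vhh_fc": {"hc1": ["VHH", "VHH"]},
}

MONOSPECIFIC = {"canonical", "vhh_fc"}


def format_label_for(fmt: str) -> str:
    return fmt if fmt in MONOSPECIFIC else f"bispecific:{fmt}"


# ---------------------------------------------------------------------------
# specification


@dataclass(frozen=True)
class GeneratorSpec:
    """Panel-generation parameters (defaults mirror a mixed-format
    discovery-stage campaign)."""

    n_antibodies: int = 200
    format_mix: dict = field(
        default_factory=lambda: {
            "canonical": 0.67,
            "vhh_fc": 0.19,
            "scfv_ig": 0.07,
            "dvd": 0.03,
            "kih_common_lc": 0.02,
            "bispecific_vhh_fc": 0.02,
        }
    )
    concentrations: tuple = (66.7, 667.0)
    coatings: tuple = ("BSA", "BVP")
    # ground-truth rule weights, fixed by calibrate_rule_weights targeting a
    # 45% polyreactive fraction at 667 nM on the 400-antibody reference panel
    w_charge: float = 0.1505
    w_hydro: float = 1.0031
    a_bsa_charge: float = 1.0
    a_bsa_hydro: float = 0.25
    a_bvp_charge: float = 0.7
    a_bvp_hydro: float = 1.0
    conc_exponent: float = 0.5
    noise_sigma: float = 0.25
    #: strength of the latent-trait tilt on CDR residue sampling
    trait_scale: float = 1.0
    seed: int = 0

    def validate(self) -> "GeneratorSpec":
        if abs(sum(self.format_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("format_mix proportions must sum to 1")
        unknown = set(self.format_mix) - set(FORMAT_LAYOUTS)
        if unknown:
            raise ValidationError(f"unknown format keys: {sorted(unknown)}")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not (self.a_bsa_charge > self.a_bsa_hydro):
            raise ValidationError("BSA must be charge-dominated (a_bsa_charge > a_bsa_hydro)")
        if self.a_bvp_charge <= 0 or self.a_bvp_hydro <= 0:
            raise ValidationError("BVP multipliers must both be positive")
        return self


@dataclass
class GroundTruth:
    """Per-antibody generator bookkeeping used as the test oracle."""

    format: str
    boundaries: dict  # chain slot -> [(start, end), ...]
    domains: list  # domain strings, var-slot order
    domain_charge: list  # net charge at pH 7.4 per domain
    domain_cdr_hydro: list  # mean CDR Kyte-Doolittle per domain
    charge_load: float  # q = max(0, sum of domain charges)
    hydro_load: float  # h = max(0, mean of domain CDR hydropathies)
    zq: float
    zh: float

    def to_json_dict(self) -> dict:
        d = self.__dict__.copy()
        d["boundaries"] = {k: [list(b) for b in v] for k, v in self.boundaries.items()}
        return d

    def boundaries_by_sequence(self, record) -> dict:
        """Re-key boundaries from chain slot to chain sequence (the form the
        AnnotationBackend consumes)."""
        return {
            getattr(record, slot): bounds
            for slot, bounds in self.boundaries.items()
            if getattr(record, slot) is not None
        }


# ---------------------------------------------------------------------------
# panel generation


def _sample_cdr(rng: np.random.Generator, length: int, zq: float, zh: float,
                trait_scale: float) -> str:
    logw = trait_scale * (zq * _CDR_CHARGE + zh * _CDR_KD / 4.5)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    idx = rng.choice(len(CDR_ALPHABET), size=length, p=w)
    return "".join(CDR_ALPHABET[i] for i in idx)


def _build_domain(rng: np.random.Generator, kind: str, zq: float, zh: float,
                  trait_scale: float) -> tuple[str, float]:
    """Return (domain sequence, mean CDR hydropathy)."""
    fr1, fr2, fr3, fr4 = FRAMEWORKS[kind]
    l1, l2, (lo3, hi3) = CDR_LENGTHS[kind]
    l3 = int(rng.integers(lo3, hi3 + 1))
    cdrs = [
        _sample_cdr(rng, l, zq, zh, trait_scale) for l in (l1, l2, l3)
    ]
    seq = fr1 + cdrs[0] + fr2 + cdrs[1] + fr3 + cdrs[2] + fr4
    cdr_res = "".join(cdrs)
    hydro = sum(KYTE_DOOLITTLE[c] for c in cdr_res) / len(cdr_res)
    return seq, hydro


def _assemble_chain(slot: str, fmt: str, domains: list[str]) -> tuple[str, list]:
    """Join domains with spacers appropriate for the chain; return chain and
    ground-truth (start, end) boundaries."""
    heavy = slot.startswith("hc")
    parts: list[str] = []
    bounds: list[tuple[int, int]] = []
    pos = 0
    for i, dom in enumerate(domains):
        if i > 0:
            parts.append(G4S_LINKER3)
            pos += len(G4S_LINKER3)
        parts.append(dom)
        bounds.append((pos, pos + len(dom)))
        pos += len(dom)
    tail = (CH1_STUB + HINGE_FC_STUB) if heavy else CL_STUB
    if fmt in ("vhh_fc", "bispecific_vhh_fc"):
        tail = HINGE_FC_STUB
    parts.append(tail)
    return "".join(parts), bounds


def format_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Exact integer counts by largest-remainder apportionment."""
    raw = {k: n * p for k, p in mix.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    by_frac = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:short]:
        counts[k] += 1
    return counts


def generate_panel(
    spec: GeneratorSpec,
) -> tuple[list[AntibodyRecord], dict[str, GroundTruth]]:
    """Generate a reproducible antibody panel plus ground-truth annotations.

    Every chain is verified against the built-in scanner; in the rare event a
    randomized CDR creates a spurious J-like motif, the molecule's CDRs are
    resampled so that extraction round-trips exactly on all emitted records.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scanner = MotifAnchorScanner()
    counts = format_counts(spec.n_antibodies, spec.format_mix)
    records: list[AntibodyRecord] = []
    truths: dict[str, GroundTruth] = {}
    idx = 0
    for fmt in spec.format_mix:  # insertion order: deterministic
        for _ in range(counts[fmt]):
            ab_id = f"mAb-{idx:04d}"
            idx += 1
            rec, truth = _generate_record(rng, ab_id, fmt, spec, scanner)
            records.append(rec)
            truths[ab_id] = truth
    return records, truths


def _generate_record(rng, ab_id, fmt, spec, scanner, max_tries=50):
    layout = FORMAT_LAYOUTS[fmt]
    zq = float(rng.normal())
    zh = float(rng.normal())
    for _ in range(max_tries):
        chains: dict[str, str] = {}
        boundaries: dict[str, list] = {}
        domains: list[str] = []
        dom_charge: list[float] = []
        dom_hydro: list[float] = []
        for slot, kinds in layout.items():
            doms = []
            for kind in kinds:
                seq, hydro = _build_domain(rng, kind, zq, zh, spec.trait_scale)
                doms.append(seq)
                dom_hydro.append(hydro)
                dom_charge.append(sum(CHARGE_PH74[c] for c in seq))
            chains[slot], boundaries[slot] = _assemble_chain(slot, fmt, doms)
            domains.extend(doms)
        ok = all(
            scanner.find_domains(chains[slot]) == boundaries[slot]
            for slot in chains
        ) and len(set(chains.values())) == len(chains)
        if ok:
            break
        dom_charge, dom_hydro, domains = [], [], []
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError(f"could not generate a scannable record for {ab_id}")
    record = AntibodyRecord(
        id=ab_id,
        hc1=chains["hc1"],
        lc1=chains.get("lc1"),
        hc2=chains.get("hc2"),
        lc2=chains.get("lc2"),
        format_label=format_label_for(fmt),
    ).validate()
    truth = GroundTruth(
        format=fmt,
        boundaries=boundaries,
        domains=domains,
        domain_charge=dom_charge,
        domain_cdr_hydro=dom_hydro,
        charge_load=max(0.0, sum(dom_charge)),
        hydro_load=max(0.0, sum(dom_hydro) / len(dom_hydro)),
        zq=zq,
        zh=zh,
    )
    return record, truth


# ---------------------------------------------------------------------------
# assay simulation


def propensity(truth: GroundTruth, coating: str, spec: GeneratorSpec) -> float:
    """Coating-specific binding propensity of one antibody."""
    if coating == "BSA":
        ac, ah = spec.a_bsa_charge, spec.a_bsa_hydro
    elif coating == "BVP":
        ac, ah = spec.a_bvp_charge, spec.a_bvp_hydro
    else:
        raise ValidationError(f"unknown coating {coating!r}")
    return (
        ac * spec.w_charge * truth.charge_load
        + ah * spec.w_hydro * truth.hydro_load
    )


def fold_over_control(
    truth: GroundTruth, coating: str, conc_nM: float, spec: GeneratorSpec,
    eps: float = 1.0,
) -> float:
    p = propensity(truth, coating, spec)
    return 1.0 + p * (conc_nM / 667.0) ** spec.conc_exponent * eps


def simulate_assay(
    records: list[AntibodyRecord],
    truths: dict[str, GroundTruth],
    spec: GeneratorSpec,
) -> list[AssayPoint]:
    """Emit one assay point per (record, concentration, coating)."""
    rng = np.random.default_rng([spec.seed, 2718])
    points: list[AssayPoint] = []
    for rec in records:
        truth = truths[rec.id]
        for conc in spec.concentrations:
            for coating in spec.coatings:
                eps = (
                    float(np.exp(rng.normal(0.0, spec.noise_sigma)))
                    if spec.noise_sigma > 0
                    else 1.0
                )
                fold = fold_over_control(truth, coating, conc, spec, eps)
                points.append(
                    AssayPoint(
                        antibody=rec,
                        concentration_nM=float(conc),
                        coating=coating,
                        fold_over_control=fold,
                        label=encode_label(fold),
                    )
                )
    return points


# ---------------------------------------------------------------------------
# calibration


def prevalence_at_reference(spec: GeneratorSpec, truths=None) -> float:
    """Noise-free fraction of polyreactive points at 667 nM (both coatings)."""
    if truths is None:
        _, truths = generate_panel(spec)
    flags = [
        propensity(t, coat, spec) > 1.0
        for t in truths.values()
        for coat in spec.coatings
    ]
    return float(np.mean(flags))


def calibrate_rule_weights(
    spec: GeneratorSpec, target: float = 0.45, tol: float = 0.01,
    n_panel: int = 400,
) -> GeneratorSpec:
    """Rescale (w_charge, w_hydro) jointly so the noise-free polyreactivity
    prevalence at 667 nM hits *target* on a reference panel.

    Keeps the charge:hydro ratio fixed; bisection on the common multiplier.
    """
    probe = replace(spec, n_antibodies=n_panel)
    _, truths = generate_panel(probe)
    base = np.array(
        [
            [
                propensity(t, coat, replace(probe, w_charge=1.0, w_hydro=0.0)),
                propensity(t, coat, replace(probe, w_charge=0.0, w_hydro=1.0)),
            ]
            for t in truths.values()
            for coat in probe.coatings
        ]
    )
    contrib = base @ np.array([spec.w_charge, spec.w_hydro])

    def prev(scale: float) -> float:
        return float(np.mean(scale * contrib > 1.0))

    lo, hi = 1e-4, 1e4
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if prev(mid) < target:
            lo = mid
        else:
            hi = mid
        if abs(prev(mid) - target) <= tol:
            break
    scale = math.sqrt(lo * hi)
    return replace(
        spec, w_charge=spec.w_charge * scale, w_hydro=spec.w_hydro * scale
    )


# ---------------------------------------------------------------------------
# serialization


def truths_to_json(truths: dict[str, GroundTruth]) -> str:
    return json.dumps({k: t.to_json_dict() for k, t in truths.items()}, indent=1)


def truths_from_json(text: str) -> dict[str, GroundTruth]:
    raw = json.loads(text)
    out = {}
    for k, d in raw.items():
        d = dict(d)
        d["boundaries"] = {
            slot: [tuple(b) for b in bs] for slot, bs in d["boundaries"].items()
        }
        out[k] = GroundTruth(**d)
    return out
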