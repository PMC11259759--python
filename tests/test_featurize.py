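"""Condition encoders, G4S concatenation, location matrix, input1 assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyreact.embed import MockEmbedder
from polyreact.errors import LengthError, ValidationError
from polyreact.featurize import (
    EncodingConfig,
    assemble_input1,
    build_location_matrix,
    encode_coating,
    encode_label,
    featurize_points,
    g4s_concatenate,
    normalize_concentration,
)
from polyreact.numbering import extract_variable_domains


class TestNormalizeConcentration:
    @pytest.mark.parametrize("conc, expected", [
        (667.0, 0.0),
        (66.7, 1.0 - math.log(66.7) / math.log(667.0)),   # 0.35409...
        (6.67, 1.0 - math.log(6.67) / math.log(667.0)),   # 0.70818...
        (1.0, 1.0),
    ])
    def test_reference_values(self, conc, expected):
        assert normalize_concentration(conc) == pytest.approx(expected, abs=1e-12)

    def test_clamped_outside_assay_range(self):
        assert normalize_concentration(1e5) == 0.0
        assert normalize_concentration(0.01) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            normalize_concentration(0.0)

    @given(st.floats(min_value=1.0, max_value=666.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing(self, c):
        assert normalize_concentration(c) > normalize_concentration(c + 1.0)


@pytest.mark.parametrize("coating, code", [
    ("BSA", 0), ("BVP", 1), ("bvp", 1), (" bsa ", 0),
])
def test_encode_coating(coating, code):
    assert encode_coating(coating) == code


def test_encode_coating_rejects_unknown():
    with pytest.raises(ValidationError):
        encode_coating("PBS")


@pytest.mark.parametrize("fold, label", [
    (0.0, 0), (2.0, 0), (2.0001, 1), (50.0, 1),
])
def test_encode_label_threshold(fold, label):
    assert encode_label(fold) == label


def test_encode_label_rejects_negative():
    with pytest.raises(ValidationError):
        encode_label(-0.5)


class TestG4S:
    def test_same_chain_domains_joined(self, domain_sets, small_panel):
        records, truths = small_panel
        cfg = EncodingConfig(scheme="g4s")
        rec = next(r for r in records if r.format_label == "bispecific:scfv_ig")
        ds = domain_sets[rec.id]
        seqs = g4s_concatenate(ds, cfg)
        d = truths[rec.id].domains
        assert seqs[0] == d[0] + "GGGGS" + d[1]  # fused heavy-chain domains
        assert seqs[1] == d[2]  # single VL passes through unlinked
        assert len(seqs[0]) == len(d[0]) + 5 + len(d[1])

    def test_canonical_passes_through(self, domain_sets, small_panel):
        records, truths = small_panel
        rec = next(r for r in records if r.format_label == "canonical")
        seqs = g4s_concatenate(domain_sets[rec.id], EncodingConfig(scheme="g4s"))
        assert seqs == truths[rec.id].domains

    def test_linker_removal_reconstructs_domains(self, domain_sets):
        cfg = EncodingConfig(scheme="g4s")
        for ds in domain_sets.values():
            doms = ds.domains()
            for slot, indices in ds.per_chain_groups.items():
                fused = g4s_concatenate(ds, cfg)
                chain_seq = fused[
                    list(ds.per_chain_groups).index(slot)
                ]
                offset = 0
                for j, i in enumerate(indices):
                    if j > 0:
                        offset += len(cfg.g4s_linker)
                    dom = doms[i - 1]
                    assert chain_seq[offset : offset + len(dom)] == dom
                    offset += len(dom)

    def test_over_capacity_names_chain(self, domain_sets, small_panel):
        records, _ = small_panel
        rec = next(r for r in records if r.format_label == "bispecific:dvd")
        cfg = EncodingConfig(scheme="g4s", g4s_chain_capacity=100)
        with pytest.raises(LengthError, match="hc1"):
            g4s_concatenate(domain_sets[rec.id], cfg)


def test_location_matrix_examples(domain_sets, small_panel):
    records, _ = small_panel
    by_fmt = {r.format_label: r for r in records}
    assert build_location_matrix(domain_sets[by_fmt["canonical"].id]).tolist() == [1, 2, 0, 0]
    assert build_location_matrix(
        domain_sets[by_fmt["bispecific:bispecific_vhh_fc"].id]
    ).tolist() == [1, 1, 0, 0]
    assert build_location_matrix(domain_sets[by_fmt["vhh_fc"].id]).tolist() == [1, 0, 0, 0]


class TestAssembleInput1:
    def test_residue_axis_536_with_two_special_tokens(self):
        assert EncodingConfig(special_tokens_per_domain=2).residue_axis == 536

    def test_residue_axis_532_with_one_special_token(self):
        assert EncodingConfig(special_tokens_per_domain=1).residue_axis == 532

    def test_empty_slots_are_zero_bands(self, mock_embedder, domain_sets,
                                        small_panel, encoding):
        records, _ = small_panel
        rec = next(r for r in records if r.format_label == "canonical")
        ds = domain_sets[rec.id]
        mats = [mock_embedder.embed(d) if d else None for d in ds.domains()]
        block = assemble_input1(mats, encoding)
        assert block.shape == (536, 32, 1)
        assert np.all(block[268:] == 0)  # var3/var4 bands empty

    def test_zero_padding_preserves_norm(self, mock_embedder, encoding):
        mats = [mock_embedder.embed("ACDEF" * 20), None,
                mock_embedder.embed("KLMNP" * 15), None]
        block = assemble_input1(mats, encoding)
        expect = sum(np.linalg.norm(m) ** 2 for m in mats if m is not None)
        assert np.linalg.norm(block) ** 2 == pytest.approx(expect, rel=1e-5)

    def test_over_capacity_domain_rejected(self, mock_embedder):
        cfg = EncodingConfig(max_domain_len=50)
        with pytest.raises(LengthError):
            assemble_input1([mock_embedder.embed("A" * 60)], cfg)


def test_featurize_points_shapes(assay_points, domain_sets, mock_embedder,
                                 encoding):
    batch = featurize_points(assay_points, domain_sets, mock_embedder, encoding)
    n = len(assay_points)
    assert batch.x1.shape == (n, 536, 32)
    assert batch.x2.shape == batch.x3.shape == (n,)
    assert batch.x4.shape == (n, 4)
    assert set(np.unique(batch.x2)) <= {0.0, 1.0}
    assert batch.x3.min() >= 0 and batch.x3.max() <= 1


def test_featurize_points_g4s_has_no_location_input(assay_points, domain_sets,
                                                    mock_embedder):
    cfg = EncodingConfig(scheme="g4s")
    batch = featurize_points(assay_points[:8], domain_sets, mock_embedder, cfg)
    assert batch.x4 is None
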