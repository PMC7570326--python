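import hashlib
import io

import matplotlib.pyplot as plt
import numpy as np
import pytest

from alnspace import (Alignment, CouplingSet, column_profiles, hamming_matrix,
                      pairwise_identity_matrix, read_annotations,
                      reference_mask)
from alnspace.column_stats import MAX_BITS, ReferenceMask
from alnspace.errors import CouplingPositionError
from alnspace.render import (get_scheme, render_coupling_overlay,
                             render_identity_heatmap, render_logo,
                             render_pixel_view, render_sequence_space)
from alnspace.seqspace import Embedding, EmbeddingConfig


@pytest.fixture(autouse=True)
def close_figures():
    yield
    plt.close("all")


class TestSchemes:
    @pytest.mark.parametrize("name", ["aa_properties", "hydrophobicity",
                                      "mutation_vs_reference"])
    def test_palette_covers_full_alphabet(self, name):
        scheme = get_scheme(name)
        assert scheme.lut().shape == (22, 3)

    def test_hydrophobicity_red_to_blue(self):
        pal = get_scheme("hydrophobicity").palette
        r, g, b = pal["I"]          # most hydrophobic -> red end
        assert r > b
        r, g, b = pal["R"]          # most hydrophilic -> blue end
        assert b > r

    def test_only_mutation_scheme_is_reference_dependent(self):
        assert get_scheme("mutation_vs_reference").reference_dependent
        assert not get_scheme("aa_properties").reference_dependent


class TestPixelView:
    def test_pixels_equal_palette_lookup(self):
        aln = Alignment(ids=["a", "b"], seqs=["ACD", "A-D"])
        scheme = get_scheme("aa_properties")
        img = render_pixel_view(aln, scheme, cell_px=1)
        arr = np.asarray(img)
        assert arr.shape == (2, 3, 3)
        for r, seq in enumerate(aln.seqs):
            for c, ch in enumerate(seq):
                assert tuple(arr[r, c]) == scheme.palette[ch]

    def test_cell_px_scales_dimensions(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACDE"), 50)) for _ in range(100)]
        aln = Alignment(ids=[f"s{i}" for i in range(100)], seqs=seqs)
        img = render_pixel_view(aln, "aa_properties", cell_px=2)
        assert img.size == (100, 200)  # PIL reports (width, height)

    def test_mutation_scheme_desaturates_matches(self):
        aln = Alignment(ids=["r", "same", "diff"], seqs=["AAA", "AAA", "CCC"])
        img = render_pixel_view(aln, "mutation_vs_reference", cell_px=1)
        arr = np.asarray(img).astype(int)
        scheme = get_scheme("mutation_vs_reference")
        full = np.array(scheme.palette["A"])
        # reference row keeps full saturation; identical row is lighter
        assert tuple(arr[0, 0]) == tuple(full)
        assert (arr[1, 0] >= full).all() and (arr[1] != arr[0]).any()
        assert tuple(arr[2, 0]) == scheme.palette["C"]

    def test_byte_identical_across_runs(self, family):
        aln, _ = family
        bufs = []
        for _ in range(2):
            img = render_pixel_view(aln, "aa_properties", cell_px=2)
            buf = io.BytesIO()
            img.save(buf, format="PNG")
            bufs.append(hashlib.sha256(buf.getvalue()).hexdigest())
        assert bufs[0] == bufs[1]

    def test_zero_cell_px_rejected(self):
        aln = Alignment(ids=["a"], seqs=["A"])
        with pytest.raises(ValueError):
            render_pixel_view(aln, "aa_properties", cell_px=0)


class TestLogo:
    def test_letter_stacks_sum_to_info_bits(self):
        seqs = ["AAAC", "AAAC", "AACC", "CACC"]
        aln = Alignment(ids=list("abcd"), seqs=seqs)
        profiles = column_profiles(aln)
        fig = render_logo(profiles)
        ax = fig.axes[-1]
        # group glyph patches by column and compare stack heights to info
        tops = {k: 0.0 for k in range(len(profiles))}
        for patch in ax.patches:
            x0, y0, x1, y1 = patch.get_path().get_extents().extents
            col = int(x0)
            tops[col] = max(tops[col], y1)
        for k, prof in enumerate(profiles):
            assert tops[k] == pytest.approx(prof.info_bits, abs=1e-6)

    def test_zero_information_column_empty_stack(self):
        aln = Alignment(ids=[f"s{i}" for i in range(20)],
                        seqs=list("ACDEFGHIKLMNPQRSTVWY"))
        fig = render_logo(column_profiles(aln))
        assert len(fig.axes[-1].patches) == 0

    def test_axis_limits_in_bits(self):
        aln = Alignment(ids=["a", "b"], seqs=["AA", "AA"])
        fig = render_logo(column_profiles(aln))
        assert fig.axes[-1].get_ylim() == (0.0, MAX_BITS)


class TestHeatmap:
    def test_identical_sequences_uniform_max_color(self):
        aln = Alignment(ids=list("abcd"), seqs=["ACDE"] * 4)
        m = pairwise_identity_matrix(aln)
        arr = np.asarray(render_identity_heatmap(m))
        assert (arr == arr[0, 0]).all()

    def test_block_structure_visible(self, family):
        aln, table = family
        m = pairwise_identity_matrix(aln)
        arr = np.asarray(render_identity_heatmap(m)).astype(float)
        labels = table.data["subfamily"].to_numpy()
        same = labels[:, None] == labels[None, :]
        darkness = 255.0 - arr.mean(axis=-1)  # darker = more identical
        assert darkness[same].mean() > darkness[~same].mean()

    def test_identity_permutation_matches_unpermuted(self, family):
        aln, _ = family
        m = pairwise_identity_matrix(aln)
        base = np.asarray(render_identity_heatmap(m))
        same = np.asarray(render_identity_heatmap(m, order=list(range(m.n))))
        assert np.array_equal(base, same)

    def test_rendering_leaves_matrix_untouched(self, family):
        aln, _ = family
        m = pairwise_identity_matrix(aln)
        before = hashlib.sha256(m.values.tobytes()).hexdigest()
        render_identity_heatmap(m, order=list(np.random.permutation(m.n)))
        assert hashlib.sha256(m.values.tobytes()).hexdigest() == before

    def test_bad_permutation_rejected(self, family):
        aln, _ = family
        m = pairwise_identity_matrix(aln)
        with pytest.raises(ValueError):
            render_identity_heatmap(m, order=[0] * m.n)


class TestSequenceSpace:
    @pytest.fixture
    def embedding(self):
        rng = np.random.default_rng(0)
        coords = rng.random((120, 2))
        return Embedding(coords=coords, config=EmbeddingConfig(),
                         order=list(range(120)))

    def test_categorical_coloring_has_legend(self, embedding, family):
        aln, table = family
        fig = render_sequence_space(embedding, table, "subfamily", ids=aln.ids)
        ax = fig.axes[0]
        legend_texts = [t.get_text() for t in ax.get_legend().get_texts()]
        assert legend_texts == [f"subfamily_{i}" for i in (1, 2, 3)]
        total = sum(len(c.get_offsets()) for c in ax.collections)
        assert total == aln.n_seqs

    def test_no_annotations_single_color(self, embedding):
        fig = render_sequence_space(embedding)
        assert len(fig.axes[0].collections) == 1

    def test_constant_numeric_key_no_crash(self, embedding, family):
        aln, _ = family
        ann = read_annotations(io.StringIO(
            "id\tw\n" + "".join(f"{sid}\t1.0\n" for sid in aln.ids)))
        fig = render_sequence_space(embedding, ann, "w", ids=aln.ids)
        assert fig is not None

    def test_unknown_key_rejected(self, embedding, family):
        aln, table = family
        with pytest.raises(KeyError):
            render_sequence_space(embedding, table, "nope", ids=aln.ids)

    def test_three_dimensional_two_panels(self):
        rng = np.random.default_rng(1)
        emb = Embedding(coords=rng.random((30, 3)),
                        config=EmbeddingConfig(n_components=3),
                        order=list(range(30)))
        fig = render_sequence_space(emb)
        assert len(fig.axes) == 2


class TestCouplingOverlay:
    def test_top_k_arcs_drawn(self):
        mask = ReferenceMask(columns=list(range(20)),
                             ref_positions=list(range(1, 21)))
        cs = CouplingSet(pairs=[(1, 5, 2.0), (2, 8, 1.0), (3, 9, 3.0)])
        fig = render_coupling_overlay(mask, cs, top_k=2)
        assert len(fig.axes[0].lines) == 2

    def test_masked_position_skipped_with_warning(self, caplog):
        # displayed columns cover reference positions 1..4 and 6..10 only
        mask = ReferenceMask(columns=[0, 1, 2, 3, 5, 6, 7, 8, 9],
                             ref_positions=[1, 2, 3, 4, 6, 7, 8, 9, 10])
        cs = CouplingSet(pairs=[(1, 5, 2.0), (2, 8, 1.0)])
        with caplog.at_level("WARNING"):
            fig = render_coupling_overlay(mask, cs, top_k=5, ref_length=10)
        assert len(fig.axes[0].lines) == 1
        assert "skipped" in caplog.text

    def test_out_of_range_position_errors(self):
        mask = ReferenceMask(columns=[0, 1], ref_positions=[1, 2])
        cs = CouplingSet(pairs=[(1, 7, 1.0)])
        with pytest.raises(CouplingPositionError):
            render_coupling_overlay(mask, cs, top_k=1)

    def test_top_k_beyond_available_draws_all(self):
        mask = ReferenceMask(columns=list(range(10)),
                             ref_positions=list(range(1, 11)))
        cs = CouplingSet(pairs=[(1, 5, 2.0)])
        fig = render_coupling_overlay(mask, cs, top_k=99)
        assert len(fig.axes[0].lines) == 1
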