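"""Chromatogram QQC: ABIF round trips, read anchoring, base
distributions and divergence scores."""

import numpy as np
import pytest

from ggmut import (
    BaseDistribution,
    QqcError,
    compare_to_degeneracy,
    extract_distributions,
    locate_randomized_positions,
    read_abif,
)
from ggmut import fixtures, qqc


RANDOMIZED = {p: "NDT" for p in fixtures.SATURATION_CASE_POSITIONS}


@pytest.fixture(scope="module")
def noisy_trace_file(tmp_path_factory, saturation_cds):
    path = tmp_path_factory.mktemp("abif") / "pool.ab1"
    trace = fixtures.pooled_trace(saturation_cds, RANDOMIZED,
                                  noise_sigma=0.1, seed=42)
    fixtures.write_abif(path, trace)
    return path, trace


def test_abif_write_read_round_trip(noisy_trace_file):
    path, trace = noisy_trace_file
    got = read_abif(path)
    assert got.basecalls == trace.basecalls
    # intensities survive the int16 round trip
    assert np.allclose(got.channels, np.round(trace.channels), atol=1.0)
    assert len(got.peak_locations) == len(trace.basecalls)


def test_truncated_file_is_a_format_error(tmp_path, noisy_trace_file):
    path, _ = noisy_trace_file
    bad = tmp_path / "trunc.ab1"
    bad.write_bytes(path.read_bytes()[:100])
    with pytest.raises(QqcError, match="not an ABIF"):
        read_abif(bad)
    notab = tmp_path / "nope.ab1"
    notab.write_bytes(b"this is not a chromatogram")
    with pytest.raises(QqcError, match="not an ABIF"):
        read_abif(notab)


def test_equal_peaks_give_uniform_proportions(saturation_cds):
    trace = qqc.ChromatogramTrace(
        np.full((9, 4), 250.0), "ATGAAATAA", np.arange(9)
    )
    dists = extract_distributions(trace, {2: (3, 4, 5)})
    for d in dists:
        assert d.proportions == pytest.approx((0.25,) * 4)


def test_locate_forward_read_covers_all_sites(saturation_cds,
                                              saturation_design,
                                              noisy_trace_file):
    path, _ = noisy_trace_file
    trace = read_abif(path)
    pos = locate_randomized_positions(trace, saturation_cds,
                                      saturation_design, "forward")
    assert sorted(pos) == sorted(RANDOMIZED)
    for ci, idxs in pos.items():
        assert idxs == tuple((ci - 1) * 3 + k for k in range(3))


def test_reverse_read_maps_to_same_codons(saturation_cds, saturation_design):
    """Coordinate-reflection oracle: a reverse read of the same construct
    yields the identical codon -> trace-position mapping after
    reflection."""
    trace_r = fixtures.pooled_trace(saturation_cds, RANDOMIZED,
                                    noise_sigma=0.0, seed=1,
                                    direction="reverse")
    trace = qqc.ChromatogramTrace(
        trace_r.channels, trace_r.basecalls,
        np.arange(len(trace_r.basecalls)),
    )
    pos = locate_randomized_positions(trace, saturation_cds,
                                      saturation_design, "reverse")
    n = len(saturation_cds)
    for ci, idxs in pos.items():
        expect = tuple(n - 1 - ((ci - 1) * 3 + k) for k in range(3))
        assert idxs == expect


def test_unrelated_sequence_does_not_match(saturation_cds, saturation_design):
    other = fixtures.random_cds(300, seed=1234)
    trace_o = fixtures.pooled_trace(other, {}, noise_sigma=0.0, seed=0)
    trace = qqc.ChromatogramTrace(
        trace_o.channels, trace_o.basecalls,
        np.arange(len(trace_o.basecalls)),
    )
    with pytest.raises(QqcError, match="does not match"):
        locate_randomized_positions(trace, saturation_cds,
                                    saturation_design, "forward")


def test_dead_peak_is_reported(saturation_cds):
    channels = np.full((9, 4), 100.0)
    channels[4] = 0.0
    trace = qqc.ChromatogramTrace(channels, "ATGAAATAA", np.arange(9))
    with pytest.raises(QqcError, match="dead peak"):
        extract_distributions(trace, {2: (3, 4, 5)})


class TestDivergence:
    def test_perfect_uniform_vs_n_scores_zero(self):
        d = BaseDistribution(1, 1, (0.25, 0.25, 0.25, 0.25))
        assert compare_to_degeneracy(d, "NDT") == pytest.approx(0.0)

    def test_single_base_vs_n_scores_three_quarters(self):
        d = BaseDistribution(1, 1, (0.0, 0.0, 0.0, 1.0))
        assert compare_to_degeneracy(d, "NDT") == pytest.approx(0.75)

    def test_tv_against_uniform_over_four_is_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.dirichlet(np.ones(4))
            d = BaseDistribution(1, 1, tuple(p))
            assert compare_to_degeneracy(d, "NNN") <= 0.75 + 1e-12

    def test_invariant_t_position(self):
        d = BaseDistribution(1, 3, (0.0, 0.0, 0.0, 1.0))
        assert compare_to_degeneracy(d, "NDT") == pytest.approx(0.0)


def test_mixture_recovery_within_tolerance(saturation_cds, saturation_design,
                                           noisy_trace_file):
    """Full QQC path on a noisy pooled trace recovers the NDT marginals
    within 0.05 total variation at every randomized position."""
    path, _ = noisy_trace_file
    dists, table = qqc.analyze(path, saturation_cds, saturation_design,
                               "forward")
    assert len(dists) == 15  # 5 codons x 3 offsets
    assert table["tv_score"].max() <= 0.05
    off3 = table[table.offset == 3]
    assert (off3["T"] == 1.0).all()  # T invariant in NDT
    assert (off3[["A", "C", "G"]] == 0.0).all().all()
    # simplex invariant
    assert np.allclose(table[list("ACGT")].sum(axis=1), 1.0, atol=2e-4)


def test_forward_and_reverse_reads_agree_noise_free(saturation_cds,
                                                    saturation_design,
                                                    tmp_path):
    paths = {}
    for direction in ("forward", "reverse"):
        trace = fixtures.pooled_trace(saturation_cds, RANDOMIZED,
                                      noise_sigma=0.0, seed=3,
                                      direction=direction)
        p = tmp_path / f"{direction}.ab1"
        fixtures.write_abif(p, trace)
        paths[direction] = p
    _, fwd = qqc.analyze(paths["forward"], saturation_cds,
                         saturation_design, "forward")
    _, rev = qqc.analyze(paths["reverse"], saturation_cds,
                         saturation_design, "reverse")
    diff = np.abs(fwd[list("ACGT")].values - rev[list("ACGT")].values)
    assert diff.max() <= 0.01


def test_report_renders_pies_and_consistent_csv(saturation_cds,
                                                saturation_design,
                                                noisy_trace_file, tmp_path):
    path, _ = noisy_trace_file
    dists, _ = qqc.analyze(path, saturation_cds, saturation_design, "forward")
    fig1 = tmp_path / "a.png"
    fig2 = tmp_path / "b.png"
    csv = tmp_path / "t.csv"
    f, table = qqc.render_qqc_report(dists, {p: "NDT" for p in RANDOMIZED},
                                     fig1, csv)
    assert len(f.axes) == 15  # one pie per randomized position
    qqc.render_qqc_report(dists, {p: "NDT" for p in RANDOMIZED}, fig2)
    assert fig1.read_bytes() == fig2.read_bytes()
    loaded = __import__("pandas").read_csv(csv)
    assert np.allclose(loaded[list("ACGT")].sum(axis=1), 1.0, atol=2e-3)
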