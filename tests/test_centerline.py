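import itertools

import numpy as np
import pytest
from scipy import ndimage as ndi

from conftest import blob_mask, count_components
from lungdot.centerline import (
    NEIGHBOR_OFFSETS,
    LineFit,
    Skeleton,
    fill_gaps,
    fit_deviation,
    fit_line_local,
    neighbor_count,
    prune_spurs,
    thin,
    transition_count,
)
from lungdot.errors import (
    InsufficientSupportError,
    InvalidParameterError,
    VerticalLineError,
)
from lungdot.phantoms import make_vessel_phantom
from lungdot.preprocess import extract_soft_tissue

FIG5_NEIGHBORHOOD = (0, 1, 0, 1, 1, 0, 1, 0)


class TestNeighborOperators:
    def test_neighbor_count_all_zero(self):
        assert neighbor_count((0,) * 8) == 0

    def test_neighbor_count_all_one(self):
        assert neighbor_count((1,) * 8) == 8

    def test_worked_example(self):
        assert neighbor_count(FIG5_NEIGHBORHOOD) == 4
        assert transition_count(FIG5_NEIGHBORHOOD) == 3

    def test_transition_all_zero(self):
        assert transition_count((0,) * 8) == 0

    def test_transition_alternating(self):
        assert transition_count((1, 0, 1, 0, 1, 0, 1, 0)) == 4

    def test_exhaustive_oracle(self):
        # brute-force over all 256 neighborhoods against the raw definitions
        for bits in itertools.product((0, 1), repeat=8):
            assert neighbor_count(bits) == sum(bits)
            cyc = bits + (bits[0],)
            expected_t = sum(
                1 for a, b in zip(cyc, cyc[1:]) if a == 0 and b == 1
            )
            assert transition_count(bits) == expected_t

    def test_bad_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            neighbor_count((0, 1, 2, 0, 0, 0, 0, 0))
        with pytest.raises(InvalidParameterError):
            transition_count((0, 1))


def reference_thin(mask: np.ndarray) -> np.ndarray:
    """Pixel-by-pixel reference implementation of the thinning rules."""
    img = mask.astype(np.uint8).copy()

    def one_pass(step):
        pad = np.pad(img, 1)
        doomed = []
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                if img[r, c] == 0:
                    continue
                nb = [pad[r + 1 + dr, c + 1 + dc] for dr, dc in NEIGHBOR_OFFSETS]
                n = sum(nb)
                t = sum(nb[i] == 0 and nb[(i + 1) % 8] == 1 for i in range(8))
                if not (2 <= n <= 6 and t == 1):
                    continue
                p2, _, p4, _, p6, _, p8, _ = nb
                if step == 1 and p2 * p4 * p6 == 0 and p4 * p6 * p8 == 0:
                    doomed.append((r, c))
                elif step == 2 and p2 * p4 * p8 == 0 and p2 * p6 * p8 == 0:
                    doomed.append((r, c))
        for r, c in doomed:
            img[r, c] = 0
        return len(doomed)

    while one_pass(1) + one_pass(2):
        pass
    out = img.astype(bool)
    # re-seed fully eroded components at their innermost pixel, as thin() does
    labeled, n = ndi.label(mask, structure=np.ones((3, 3), int))
    for comp in range(1, n + 1):
        sel = labeled == comp
        if not (out & sel).any():
            dist = ndi.distance_transform_edt(sel)
            out[np.unravel_index(int(dist.argmax()), out.shape)] = True
    return out


class TestThin:
    def test_isolated_pixel_unchanged(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert thin(mask).mask[4, 4]
        assert thin(mask).mask.sum() == 1

    def test_bar_thins_to_path(self):
        mask = np.zeros((9, 26), bool)
        mask[3:6, 3:23] = True
        sk = thin(mask)
        assert sk.mask.sum() == pytest.approx(20, abs=3)
        assert len(sk.endpoints) == 2
        assert count_components(sk.mask) == 1

    def test_matches_reference_implementation(self):
        for seed in range(8):
            mask = blob_mask(seed, shape=(48, 48))
            np.testing.assert_array_equal(thin(mask).mask, reference_thin(mask))

    def test_empty_mask(self):
        sk = thin(np.zeros((6, 6), bool))
        assert not sk.mask.any()
        assert len(sk.pixels) == 0

    def test_idempotent(self):
        for seed in (0, 5, 11):
            sk = thin(blob_mask(seed))
            np.testing.assert_array_equal(thin(sk.mask).mask, sk.mask)

    def test_subset_of_input(self):
        mask = blob_mask(2)
        assert not (thin(mask).mask & ~mask).any()

    @pytest.mark.parametrize("seed", range(100))
    def test_component_preservation(self, seed):
        mask = blob_mask(seed, shape=(64, 64))
        assert count_components(thin(mask).mask) == count_components(mask)


class TestPruneSpurs:
    @staticmethod
    def _path_with_spur():
        mask = np.zeros((16, 50), bool)
        mask[10, 5:46] = True  # main path
        mask[7:10, 25] = True  # 3-px spur
        return Skeleton(mask)

    def test_zero_iterations_identity(self):
        sk = self._path_with_spur()
        np.testing.assert_array_equal(prune_spurs(sk, 0).mask, sk.mask)

    def test_spur_removed_main_path_kept(self):
        pruned = prune_spurs(self._path_with_spur(), 3)
        # outer spur pixels deleted endpoint-by-endpoint; the base pixel
        # touches three path pixels, is never an endpoint, and may survive
        assert not pruned.mask[7:9, 25].any()
        assert pruned.mask[7:10, 25].sum() <= 1
        # main path endpoints protected (long branch): retract by <= iterations
        assert pruned.mask[10, 5:46].sum() >= 41 - 3

    def test_spur_free_path_protected(self):
        mask = np.zeros((8, 40), bool)
        mask[4, 2:38] = True
        pruned = prune_spurs(Skeleton(mask), 5)
        np.testing.assert_array_equal(pruned.mask, mask)

    def test_negative_iterations_rejected(self):
        with pytest.raises(InvalidParameterError):
            prune_spurs(self._path_with_spur(), -1)


class TestFillGaps:
    def test_no_removed_regions_identity(self):
        mask = blob_mask(1)
        out = fill_gaps(mask, [])
        np.testing.assert_array_equal(out.data, mask)

    def test_x_vessel_reconnected(self):
        img = make_vessel_phantom("X", shape=(128, 128))
        mask = extract_soft_tissue(img, 130).data.copy()
        center = np.array([63.5, 63.5])
        rr, cc = np.nonzero(mask)
        hole = np.hypot(rr - center[0], cc - center[1]) <= 10
        removed = np.column_stack((rr[hole], cc[hole]))
        mask[rr[hole], cc[hole]] = False
        assert count_components(mask) == 4
        out = fill_gaps(mask, [removed])
        assert count_components(out.data) == 1
        # bridges pass through the removed center
        assert out.data[63, 63] or out.data[64, 64] or out.data[63, 64] or out.data[64, 63]

    def test_distant_components_not_bridged(self):
        mask = np.zeros((40, 120), bool)
        mask[20, 5:15] = True
        mask[20, 105:115] = True
        removed = np.column_stack(([20, 20], [58, 62]))
        out = fill_gaps(mask, [removed], max_gap_px=5)
        assert count_components(out.data) == 2

    def test_never_increases_components(self):
        for seed in range(10):
            mask = blob_mask(seed)
            rr, cc = np.nonzero(mask)
            if len(rr) == 0:
                continue
            removed = np.column_stack((rr[:5], cc[:5]))
            work = mask.copy()
            work[rr[:5], cc[:5]] = False
            out = fill_gaps(work, [removed])
            assert count_components(out.data) <= count_components(work)


class TestFitLineLocal:
    def test_horizontal_row(self):
        mask = np.zeros((20, 30), bool)
        mask[10, 5:25] = True
        fit = fit_line_local(Skeleton(mask), (10, 15), window=15)
        assert fit.alpha**2 + fit.beta**2 == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(0.0, abs=1e-9)
        assert fit.intercept == pytest.approx(10.0, abs=1e-9)
        assert fit.gamma / fit.beta == pytest.approx(-10.0, abs=1e-9)

    def test_diagonal(self):
        mask = np.zeros((30, 30), bool)
        for i in range(5, 25):
            mask[i, i] = True
        fit = fit_line_local(Skeleton(mask), (15, 15), window=15)
        assert abs(fit.slope) == pytest.approx(1.0, abs=1e-6)

    def test_two_points_exact(self):
        mask = np.zeros((20, 20), bool)
        mask[3, 4] = True
        mask[11, 16] = True
        fit = fit_line_local(Skeleton(mask), (7, 10), window=5)
        assert fit.distance((3, 4)) == pytest.approx(0.0, abs=1e-9)
        assert fit.distance((11, 16)) == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_support(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 5] = True
        with pytest.raises(InsufficientSupportError):
            fit_line_local(Skeleton(mask), (5, 5))


class TestFitDeviation:
    def test_identical_replicates(self):
        fits = [LineFit(0.0, 1.0, -10.0)] * 3
        assert fit_deviation(fits) == (0.0, 0.0)

    def test_known_spread(self):
        b = 1.0 / np.sqrt(2.0)
        fits = [LineFit(-b, b, -b * g) for g in (0.0, 1.0, 2.0)]
        dslope, dint = fit_deviation(fits)
        assert dslope == pytest.approx(0.0, abs=1e-12)
        assert dint == pytest.approx(np.std([0.0, 1.0, 2.0]), rel=1e-9)
        assert dint == pytest.approx(0.8165, abs=1e-4)

    def test_two_replicates(self):
        fits = [LineFit(0.0, 1.0, 0.0), LineFit(0.0, 1.0, -2.0)]
        _, dint = fit_deviation(fits)
        assert dint == pytest.approx(1.0)

    def test_vertical_line_error(self):
        fits = [LineFit(1.0, 0.0, -3.0), LineFit(0.0, 1.0, 0.0)]
        with pytest.raises(VerticalLineError):
            fit_deviation(fits)

    def test_single_fit_rejected(self):
        with pytest.raises(InsufficientSupportError):
            fit_deviation([LineFit(0.0, 1.0, 0.0)])
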