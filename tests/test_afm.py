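"""Morphometry pipeline checks against ground truth and a brute-force
local-maximum oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import fibriq as fq
from conftest import match_detections


def gaussian_bump(shape, row, col, amplitude=10.0, sigma_px=2.5):
    gr, gc = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((gr - row) ** 2 + (gc - col) ** 2)
                              / (2 * sigma_px**2))


# --------------------------------------------------------------------------- #
# scanline flattening
# --------------------------------------------------------------------------- #

class TestFlattenScanlines:
    @pytest.mark.parametrize("order", [0, 1])
    def test_constant_image_zeroed(self, order):
        img = fq.HeightImage(np.full((16, 16), 7.3), 2.0)
        out = fq.flatten_scanlines(img, order)
        assert np.allclose(out.values, 0.0, atol=1e-9)

    @pytest.mark.parametrize("order", [0, 1])
    def test_invariance_to_row_offsets(self, order):
        rng = np.random.default_rng(0)
        base = gaussian_bump((64, 64), 30, 20) + rng.normal(0, 1, (64, 64))
        offs = rng.normal(0, 5, (64, 1))
        a = fq.flatten_scanlines(fq.HeightImage(base, 2.0), order)
        b = fq.flatten_scanlines(fq.HeightImage(base + offs, 2.0), order)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_row_medians_zero(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1, (32, 48)) + np.arange(32)[:, None] * 0.5
        out = fq.flatten_scanlines(fq.HeightImage(v, 2.0), 1)
        assert np.allclose(np.median(out.values, axis=1), 0.0, atol=1e-9)

    def test_too_narrow_rows_rejected(self):
        with pytest.raises(ValueError):
            fq.flatten_scanlines(fq.HeightImage(np.ones((4, 1)), 2.0), 1)

    def test_pipeline_invariant_to_scanline_offsets(self):
        """Detection on a rendering with strong scanline offsets matches
        detection on the offset-free rendering of the same seed."""
        lengths = [8, 10]
        base = dict(image_size=(512, 512), rng_seed=3)
        img0, _ = fq.render_chain_image(
            fq.CONTROL_PERIODICITY,
            lengths,
            fq.ChainRenderConfig(scanline_offset_sd=0.0, **base),
        )
        img5, _ = fq.render_chain_image(
            fq.CONTROL_PERIODICITY,
            lengths,
            fq.ChainRenderConfig(scanline_offset_sd=5.0, **base),
        )
        d0 = fq.detect_beads(fq.flatten_scanlines(img0, 0))
        d5 = fq.detect_beads(fq.flatten_scanlines(img5, 0))
        assert len(d0) == len(d5)
        assert np.allclose(d0[["x_nm", "y_nm"]], d5[["x_nm", "y_nm"]], atol=1e-6)


# --------------------------------------------------------------------------- #
# artifact masking and contrast inversion
# --------------------------------------------------------------------------- #

class TestMaskArtifacts:
    def test_clean_image_empty_mask(self, rendered_control):
        img, _, _ = rendered_control
        flat = fq.flatten_scanlines(img)
        assert not fq.mask_artifacts(flat).any()

    def test_injected_blobs_flagged(self):
        cfg = fq.ChainRenderConfig(image_size=(512, 512), artifact_density=3,
                                   rng_seed=21)
        img, truth = fq.render_chain_image(fq.CONTROL_PERIODICITY, [10], cfg)
        flat = fq.flatten_scanlines(img)
        mask = fq.mask_artifacts(flat)
        assert len(truth.artifacts) == 3
        labels, n = ndimage.label(mask)
        assert n >= 3
        for _, a in truth.artifacts.iterrows():
            r, c = int(a.y_nm / cfg.pixel_scale), int(a.x_nm / cfg.pixel_scale)
            assert mask[r, c]

    def test_saturated_image_fully_masked(self):
        img = fq.HeightImage(np.full((64, 64), 65535.0), 2.0)
        mask = fq.mask_artifacts(img)
        assert mask.all()
        beads = fq.detect_beads(img, mask=mask)
        assert len(beads) == 0


class TestInvertContrast:
    def test_involution(self):
        rng = np.random.default_rng(2)
        img = fq.HeightImage(rng.normal(0, 1, (32, 32)), 2.0)
        back = fq.invert_contrast(fq.invert_contrast(img))
        assert np.allclose(back.values, img.values, atol=1e-9)

    def test_constant_unchanged(self):
        img = fq.HeightImage(np.full((8, 8), 3.0), 2.0)
        assert np.allclose(fq.invert_contrast(img).values, 3.0)

    def test_detection_polarity_symmetry(self):
        v = gaussian_bump((96, 96), 48, 32)
        up = fq.detect_beads(fq.HeightImage(v, 2.0))
        down = fq.detect_beads(fq.invert_contrast(fq.HeightImage(v, 2.0)),
                               polarity="min")
        assert len(up) == len(down) == 1
        assert np.allclose(up[["x_nm", "y_nm"]], down[["x_nm", "y_nm"]], atol=1e-6)


# --------------------------------------------------------------------------- #
# bead detection
# --------------------------------------------------------------------------- #

class TestDetectBeads:
    def test_single_bump_position(self):
        v = gaussian_bump((96, 96), 48, 32)
        beads = fq.detect_beads(fq.HeightImage(v, 2.0))
        assert len(beads) == 1
        assert beads.x_nm.iloc[0] == pytest.approx(64.0, abs=2.0)
        assert beads.y_nm.iloc[0] == pytest.approx(96.0, abs=2.0)

    def test_rendered_chain_recovered(self):
        cfg = fq.ChainRenderConfig(image_size=(1024, 1024), rng_seed=13)
        img, truth = fq.render_chain_image(fq.CONTROL_PERIODICITY, [21], cfg)
        beads = fq.detect_beads(fq.flatten_scanlines(img))
        assert len(beads) == 21
        hits = match_detections(beads, truth.beads, tol_nm=cfg.pixel_scale)
        assert hits == 21

    def test_noise_only_rarely_fires(self):
        spurious = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            img = fq.HeightImage(rng.normal(0, 1, (256, 256)), 4.0)
            spurious += len(fq.detect_beads(fq.flatten_scanlines(img)))
        assert spurious / 20 <= 1.0

    def test_min_separation_precondition(self):
        img = fq.HeightImage(np.zeros((8, 8)), 4.0)
        with pytest.raises(ValueError):
            fq.detect_beads(img, min_separation=4.0)

    def test_small_smoothing_warns_and_clamps(self):
        v = gaussian_bump((64, 64), 32, 32)
        with pytest.warns(UserWarning):
            beads = fq.detect_beads(fq.HeightImage(v, 4.0), smoothing_sigma=1.0)
        assert len(beads) == 1

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        v = (gaussian_bump((128, 128), 40, 40)
             + gaussian_bump((128, 128), 70, 90)
             + rng.normal(0, 0.3, (128, 128)))
        img = fq.HeightImage(v, 2.0)
        shifted = fq.HeightImage(np.roll(v, (7, -11), axis=(0, 1)), 2.0)
        a = fq.detect_beads(img, min_prominence=1.0)
        b = fq.detect_beads(shifted, min_prominence=1.0)
        a = a.sort_values("x_nm").reset_index(drop=True)
        b = b.sort_values("x_nm").reset_index(drop=True)
        assert len(a) == len(b) == 2
        dx = (b.x_nm - a.x_nm).to_numpy()
        dy = (b.y_nm - a.y_nm).to_numpy()
        assert np.allclose(dx, -11 * 2.0, atol=0.2)
        assert np.allclose(dy, 7 * 2.0, atol=0.2)


def brute_force_detect(img, smoothing_sigma=5.0, min_separation=30.0):
    """Exhaustive reference detector: plain loops over every pixel."""
    scale = img.pixel_scale
    smooth = ndimage.gaussian_filter(img.values, smoothing_sigma / scale)
    height = smooth - float(np.median(smooth))
    med = np.median(height)
    mad = np.median(np.abs(height - med))
    prom = max(5 * 1.4826 * mad, 0.02 * height.max())
    nr, nc = height.shape
    border = int(np.ceil(2 * smoothing_sigma / scale))
    cands = []
    for r in range(nr):
        for c in range(nc):
            if (r < border or c < border
                    or r >= nr - border or c >= nc - border):
                continue
            h = height[r, c]
            if h < prom:
                continue
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (dr or dc) and 0 <= rr < nr and 0 <= cc < nc:
                        if height[rr, cc] > h:
                            ok = False
            if ok:
                cands.append((h, r, c))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept = []
    for h, r, c in cands:
        if all(np.hypot(r - kr, c - kc) * scale >= min_separation
               for _, kr, kc in kept):
            kept.append((h, r, c))
    out = []
    for h, r, c in kept:
        num_r = num_c = den = 0.0
        for rr in range(max(r - 2, 0), min(r + 3, nr)):
            for cc in range(max(c - 2, 0), min(c + 3, nc)):
                w = max(height[rr, cc], 0.0)
                num_r += w * rr
                num_c += w * cc
                den += w
        out.append((num_c / den * scale, num_r / den * scale))
    return out


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        """On small images the vectorized detector agrees with a plain
        per-pixel scan for qualifying local maxima."""
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 0.5, (64, 64))
        n_bumps = rng.integers(1, 4)
        for _ in range(n_bumps):
            r, c = rng.uniform(8, 56, 2)
            v += gaussian_bump((64, 64), r, c)
        img = fq.HeightImage(v, 2.0)
        got = fq.detect_beads(img)
        want = brute_force_detect(img)
        assert len(got) == len(want)
        for x, y in want:
            d = np.hypot(got.x_nm - x, got.y_nm - y)
            assert d.min() <= 0.5 * img.pixel_scale


# --------------------------------------------------------------------------- #
# chain linking
# --------------------------------------------------------------------------- #

class TestLinkChains:
    def test_two_parallel_lines(self):
        xs = np.arange(6) * 56.0
        beads = pd.DataFrame({
            "x_nm": np.concatenate([xs, xs]),
            "y_nm": np.concatenate([np.zeros(6), np.full(6, 5 * 125.0)]),
        })
        chains = fq.link_chains(beads, max_link=125.0)
        assert len(chains) == 2
        assert sorted(c.bead_count for c in chains) == [6, 6]
        for c in chains:
            assert np.allclose(c.repeats, 56.0)

    def test_tie_break_deterministic(self):
        # bead 0 equidistant from 1 and 2; the smaller index pair wins
        beads = pd.DataFrame({"x_nm": [0.0, 56.0, 56.0],
                              "y_nm": [0.0, 40.0, -40.0]})
        runs = [fq.link_chains(beads, max_link=80.0, max_turn=180.0)
                for _ in range(3)]
        first = runs[0]
        for r in runs[1:]:
            assert len(r) == len(first)
            for c1, c2 in zip(r, first):
                assert np.array_equal(c1.x_nm, c2.x_nm)
        # pair (0,1) sorts before (0,2) at equal distance
        chain = first[0]
        assert {tuple(p) for p in zip(chain.x_nm, chain.y_nm)} >= {(0.0, 0.0), (56.0, 40.0)}

    def test_rendered_chains_membership(self, rendered_control):
        img, truth, cfg = rendered_control
        res = fq.analyze_image(img)
        assert len(res.chains) == len(truth.chain_lengths)
        assert sorted(res.bead_counts) == sorted(truth.chain_lengths.values())

    def test_singletons_discarded(self):
        beads = pd.DataFrame({"x_nm": [0.0, 56.0, 5000.0],
                              "y_nm": [0.0, 0.0, 5000.0]})
        chains = fq.link_chains(beads)
        assert len(chains) == 1
        assert chains[0].bead_count == 2


# --------------------------------------------------------------------------- #
# measurement
# --------------------------------------------------------------------------- #

class TestMeasure:
    def test_straight_chain(self):
        c = fq.BeadChain(0, [0.0, 0.0, 0.0], [0.0, 56.0, 112.0])
        res = fq.measure([c], pixel_scale=2.0)
        assert np.allclose(res.periodicities, [56.0, 56.0])
        assert res.bead_counts.tolist() == [3]

    def test_repeat_count_is_beads_minus_one(self):
        x = np.cumsum(np.full(21, 56.0))
        res = fq.measure([fq.BeadChain(0, x, np.zeros(21))], 2.0)
        assert len(res.periodicities) == 20

    def test_short_chains_excluded(self):
        good = fq.BeadChain(0, [0.0, 56.0], [0.0, 0.0])
        bad = fq.BeadChain(1, [500.0], [500.0])
        res = fq.measure([good, bad], 2.0)
        assert len(res.chains) == 1

    def test_pooled_count_invariant(self, rendered_control):
        img, truth, _ = rendered_control
        res = fq.analyze_image(img)
        assert len(res.periodicities) == sum(res.bead_counts - 1)


# --------------------------------------------------------------------------- #
# end-to-end recovery
# --------------------------------------------------------------------------- #

class TestPipelineRecovery:
    def test_determinism(self, rendered_control):
        img, _, _ = rendered_control
        a = fq.analyze_image(img)
        b = fq.analyze_image(img)
        assert np.array_equal(a.periodicities, b.periodicities)
        assert np.array_equal(a.bead_counts, b.bead_counts)

    def test_unbiased_recovery_over_seeds(self):
        """Across 20 renderings at default noise, the pipeline recovers
        mean periodicity within 1 nm and mean bead count within 1 bead
        of the generator's truth."""
        per_bias, len_bias = [], []
        for seed in range(20):
            lengths = fq.sample_chain_lengths(*fq.CONTROL_LENGTH, 3,
                                              seed=1000 + seed)
            cfg = fq.ChainRenderConfig(rng_seed=seed)
            img, truth = fq.render_chain_image(
                fq.CONTROL_PERIODICITY, lengths, cfg)
            res = fq.analyze_image(img)
            per_bias.append(res.periodicities.mean() - truth.mean_periodicity)
            len_bias.append(res.bead_counts.mean() - truth.mean_length)
        assert abs(np.mean(per_bias)) < 1.0
        assert abs(np.mean(len_bias)) < 1.0


# --------------------------------------------------------------------------- #
# I/O round trips
# --------------------------------------------------------------------------- #

class TestHeightImageIO:
    def test_text_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        img = fq.HeightImage(rng.normal(0, 1, (32, 32)), 4.0)
        img.to_text(tmp_path / "img.txt")
        back = fq.HeightImage.from_text(tmp_path / "img.txt")
        assert back.pixel_scale == 4.0
        assert np.allclose(back.values, img.values)

    def test_tiff_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        img = fq.HeightImage(rng.normal(0, 5, (32, 32)), 2.0)
        img.to_tiff(tmp_path / "img.tif")
        back = fq.HeightImage.from_tiff(tmp_path / "img.tif")
        assert back.pixel_scale == 2.0
        # 16-bit quantization over the full height range
        step = np.ptp(img.values) / 65535
        assert np.allclose(back.values, img.values, atol=step)
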