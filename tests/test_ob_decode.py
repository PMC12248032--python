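"""Spot detection, colocalization and glomerulus identity rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orfish.ob_decode import (
    Molecule,
    Spot,
    assign_glomerulus_identity,
    colocalize,
    detect_spots,
    fit_brightness_threshold,
    relaxed_consensus,
)

PIX = (0.5, 0.1, 0.1)


def brute_force_colocalize(spots, radius=0.160, min_bits=4):
    """Independent O(n^2) grouping with the same greedy-by-brightness rule."""
    order = sorted(range(len(spots)), key=lambda i: (-spots[i].brightness, i))
    used = [False] * len(spots)
    out = []
    for i in order:
        if used[i]:
            continue
        group = []
        for j in range(len(spots)):
            if used[j]:
                continue
            if all(
                abs(spots[i].position_um[a] - spots[j].position_um[a]) <= radius
                for a in range(3)
            ):
                group.append(j)
        best = {}
        for j in group:
            b = spots[j].bit
            if b not in best or spots[j].brightness > spots[best[b]].brightness:
                best[b] = j
        if len(best) < min_bits:
            continue
        members = sorted(best.values(), key=lambda j: (-spots[j].brightness, j))[:4]
        for j in members:
            used[j] = True
        pos = tuple(
            float(np.mean([spots[j].position_um[a] for j in members])) for a in range(3)
        )
        out.append(
            (pos, tuple(sorted(spots[j].bit for j in members)),
             float(np.mean([spots[j].brightness for j in members])))
        )
    return sorted(out)


def _random_spots(rng, n, n_bits=15, extent=20.0):
    return [
        Spot(
            bit=int(rng.integers(n_bits)),
            position_um=tuple(rng.uniform(0, extent, 3)),
            brightness=float(rng.uniform(1, 10)),
        )
        for _ in range(n)
    ]


class TestDetectSpots:
    def test_blank_image_empty(self):
        assert detect_spots(np.zeros((4, 10, 10)), bit=0, intensity_threshold=0.5) == []

    def test_single_gaussian_spot_localized(self):
        img = np.zeros((7, 21, 21))
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in img.shape), indexing="ij")
        img += 10 * np.exp(-(((zz - 3) ** 2) / 2 + ((yy - 10.3) ** 2) / 4 + ((xx - 9.7) ** 2) / 4))
        spots = detect_spots(img, bit=2, intensity_threshold=1.0, pixel_size_um=PIX)
        assert len(spots) == 1
        s = spots[0]
        assert s.bit == 2
        assert abs(s.position_um[1] / PIX[1] - 0.5 - 10.3) < 1.0
        assert abs(s.position_um[2] / PIX[2] - 0.5 - 9.7) < 1.0

    def test_many_spots_recovered_subvoxel(self):
        rng = np.random.default_rng(0)
        shape = (12, 80, 80)
        img = np.zeros(shape)
        centers = []
        grid = [(z, y, x) for z in range(2, 10, 5) for y in range(5, 75, 7) for x in range(5, 75, 7)]
        rng.shuffle(grid)
        for z, y, x in grid[:100]:
            c = (z + rng.uniform(-0.3, 0.3), y + rng.uniform(-0.3, 0.3), x + rng.uniform(-0.3, 0.3))
            centers.append(c)
            zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
            img += 10 * np.exp(
                -(((zz - c[0]) ** 2) / 1.0 + ((yy - c[1]) ** 2) / 1.8 + ((xx - c[2]) ** 2) / 1.8)
            )
        spots = detect_spots(img, bit=0, intensity_threshold=2.0, pixel_size_um=(1, 1, 1))
        assert len(spots) == 100
        got = np.array([s.position_um for s in spots]) - 0.5
        want = np.array(centers)
        d = np.linalg.norm(got[:, None] - want[None], axis=2).min(axis=1)
        assert np.sqrt((d**2).mean()) < 0.5


class TestColocalize:
    def test_four_coincident_bits_form_molecule(self):
        spots = [Spot(b, (1.0, 1.0, 1.0), 5.0) for b in range(4)]
        mols = colocalize(spots)
        assert len(mols) == 1
        assert mols[0].bits == (0, 1, 2, 3)

    def test_three_bits_insufficient(self):
        spots = [Spot(b, (1.0, 1.0, 1.0), 5.0) for b in range(3)]
        assert colocalize(spots) == []

    def test_five_bits_keeps_brightest_four(self):
        spots = [Spot(b, (1.0, 1.0, 1.0), 10.0 - b) for b in range(5)]
        mols = colocalize(spots)
        assert len(mols) == 1
        assert mols[0].bits == (0, 1, 2, 3)  # bit 4 is the dimmest

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            spots = _random_spots(rng, 500, extent=10.0)
            got = sorted(
                (m.position_um, m.bits, m.brightness) for m in colocalize(spots)
            )
            want = brute_force_colocalize(spots)
            assert len(got) == len(want)
            for (p1, b1, a1), (p2, b2, a2) in zip(got, want):
                assert b1 == b2
                assert np.allclose(p1, p2)
                assert np.isclose(a1, a2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        spots = _random_spots(rng, 200, extent=5.0)
        a = sorted((m.bits, m.position_um) for m in colocalize(spots))
        shuffled = [spots[i] for i in rng.permutation(len(spots))]
        b = sorted((m.bits, m.position_um) for m in colocalize(shuffled))
        assert a == b

    def test_molecule_requires_exactly_four_distinct_bits(self):
        with pytest.raises(ValueError):
            Molecule(position_um=(0, 0, 0), bits=(1, 1, 2, 3), brightness=1.0)


class TestBrightnessThreshold:
    def test_separable_populations(self):
        rng = np.random.default_rng(1)
        b = np.concatenate([rng.normal(10, 1, 2000), rng.normal(2, 1, 2000)])
        t = np.concatenate([np.ones(2000, bool), np.zeros(2000, bool)])
        thr, keep = fit_brightness_threshold(b, t)
        assert 2 < thr < 10
        pred = b >= thr
        assert (pred == t).mean() > 0.99

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(2)
        b = rng.normal(5, 1, 2000)
        t = rng.random(2000) < 0.5
        thr, keep = fit_brightness_threshold(b, t)
        pred = b >= thr
        assert (pred == t).mean() < 0.6

    def test_single_population_warns_and_keeps_all(self):
        b = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            thr, keep = fit_brightness_threshold(b, np.ones(3, bool))
        assert thr is None
        assert keep.all()


def assignment_oracle(counts, min_count=10, enrichment=10.0):
    """One-pass rule re-implementation over a tidy count table."""
    out = {}
    for s in counts["section"].unique():
        sec = counts[counts["section"] == s]
        gloms = sec["glomerulus"].unique()
        for g in gloms:
            mine = sec[sec["glomerulus"] == g].groupby("receptor")["count"].sum()
            top = mine.idxmax()
            top_count = mine.max()
            others = sec[(sec["glomerulus"] != g) & (sec["receptor"] == top)]
            denom = max(others["count"].max() if len(others) else 0, 1)
            ok = (top_count > min_count) and (top_count > enrichment * denom)
            out[(g, s)] = top if ok else None
    return out


class TestGlomerulusAssignment:
    def test_clear_dominant_assigned_strict(self):
        counts = pd.DataFrame(
            {"glomerulus": [1, 2], "section": [0, 0], "receptor": ["A", "A"], "count": [12, 1]}
        )
        out = assign_glomerulus_identity(counts).set_index("glomerulus")
        assert out.loc[1, "receptor"] == "A"
        assert out.loc[1, "tier"] == "strict"
        assert out.loc[2, "receptor"] is None

    def test_tied_dominants_fail_enrichment(self):
        counts = pd.DataFrame(
            {"glomerulus": [1, 2], "section": [0, 0], "receptor": ["A", "A"], "count": [12, 12]}
        )
        out = assign_glomerulus_identity(counts)
        assert (out["tier"] == "none").all()

    def test_count_exactly_ten_not_assigned(self):
        counts = pd.DataFrame(
            {"glomerulus": [1], "section": [0], "receptor": ["A"], "count": [10]}
        )
        out = assign_glomerulus_identity(counts)
        assert out.iloc[0]["tier"] == "none"
        counts.loc[0, "count"] = 11
        out = assign_glomerulus_identity(counts)
        assert out.iloc[0]["tier"] == "strict"

    def test_randomized_tables_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n_glom = rng.integers(2, 6)
            n_rec = rng.integers(1, 4)
            rows = []
            for g in range(n_glom):
                for r in range(n_rec):
                    c = int(rng.choice([0, 1, 2, 5, 9, 10, 11, 12, 50, 120]))
                    if c:
                        rows.append({"glomerulus": g, "section": 0, "receptor": f"R{r}", "count": c})
            if not rows:
                continue
            counts = pd.DataFrame(rows)
            got = assign_glomerulus_identity(counts)
            oracle = assignment_oracle(counts)
            for _, row in got.iterrows():
                assert row["receptor"] == oracle[(row["glomerulus"], row["section"])]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(base=st.integers(11, 100), extra=st.integers(0, 100))
    def test_assignment_monotone_in_dominant_count(self, base, extra):
        """Raising the dominant count never revokes an assignment."""
        counts = pd.DataFrame(
            {"glomerulus": [1, 2], "section": [0, 0],
             "receptor": ["A", "A"], "count": [base, 1]}
        )
        a = assign_glomerulus_identity(counts).set_index("glomerulus").loc[1, "receptor"]
        counts.loc[0, "count"] = base + extra
        b = assign_glomerulus_identity(counts).set_index("glomerulus").loc[1, "receptor"]
        if a == "A":
            assert b == "A"


class TestRelaxedConsensus:
    @staticmethod
    def _row(bulb, rec, count, tier, x=0.0, y=0.0, z=0.0):
        return {
            "receptor": rec if tier == "strict" else None,
            "top_receptor": rec, "top_count": count, "tier": tier,
            "x": x, "y": y, "z": z,
        }

    def test_two_bulbs_consistent_position_rescued(self):
        m1 = pd.DataFrame([self._row(0, "A", 7, "none", x=0.0)])
        m2 = pd.DataFrame([self._row(1, "A", 6, "none", x=300.0)])
        out = relaxed_consensus([m1, m2])
        assert (out["tier"] == "relaxed").all()
        assert (out["receptor"] == "A").all()

    def test_no_counterpart_within_radius_stays_unassigned(self):
        m1 = pd.DataFrame([self._row(0, "A", 7, "none", x=0.0)])
        m2 = pd.DataFrame([self._row(1, "A", 6, "none", x=900.0)])
        out = relaxed_consensus([m1, m2])
        assert (out["tier"] == "none").all()

    def test_count_five_never_rescued(self):
        m1 = pd.DataFrame([self._row(0, "A", 5, "none")])
        m2 = pd.DataFrame([self._row(1, "A", 50, "strict")])
        out = relaxed_consensus([m1, m2])
        assert out[out["bulb"] == 0].iloc[0]["tier"] == "none"

    def test_single_bulb_warns(self):
        m1 = pd.DataFrame([self._row(0, "A", 7, "none")])
        with pytest.warns(UserWarning):
            out = relaxed_consensus([m1])
        assert (out["tier"] == "none").all()
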