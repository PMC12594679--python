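"""Feature detectors: manifest recovery, thresholds, classification."""

import numpy as np
import pytest

from nvumorph import (
    DetectorParams,
    LabelVolume,
    RoleMap,
    detect_detachments,
    detect_peg_sockets,
    detect_tubules,
    frequency_per_10um,
    generate_phantom,
    summarize_capillary,
)
from nvumorph.phantom import PHANTOM_LABELS

from conftest import small_detachment, small_peg, small_spec, small_tubule

L = PHANTOM_LABELS


def toy_slab(n_z=4, size=40):
    """A flat toy geometry: lumen | endothelium | BM | pericyte bands
    along y — convenient for hand-placed threshold tests."""
    voxels = np.zeros((n_z, size, size), dtype=np.uint8)
    voxels[:, :10, :] = L["lumen"]
    voxels[:, 10:25, :] = L["endothelium"]
    voxels[:, 25:30, :] = L["basement_membrane"]
    voxels[:, 30:40, :] = L["pericyte"]
    roles = RoleMap({v: k for k, v in L.items()})
    return voxels, roles


class TestPegSockets:
    def test_attached_pegs_detected_with_state(self, featured_phantom):
        spec, volume, roles, gt = featured_phantom
        events = detect_peg_sockets(volume, roles)
        assert len(events) == 2
        states = sorted(e.attachment_state for e in events)
        assert states == ["attached", "partially_detached"]

    def test_detached_peg_gap_width_measured(self, featured_phantom):
        spec, volume, roles, _ = featured_phantom
        events = detect_peg_sockets(volume, roles)
        detached = [e for e in events if e.attachment_state == "partially_detached"]
        assert len(detached) == 1
        assert detached[0].max_gap_nm == pytest.approx(30.0, abs=8.0)

    def test_z_extent_matches_planted(self, featured_phantom):
        spec, volume, roles, _ = featured_phantom
        events = sorted(detect_peg_sockets(volume, roles), key=lambda e: e.z_start)
        planted = sorted(spec.pegs, key=lambda p: p.z_center)
        for event, peg in zip(events, planted):
            assert event.z_start <= peg.z_center <= event.z_end

    def test_no_pericyte_voxels_returns_empty_with_warning(self, plain_phantom, caplog):
        volume, roles, _ = plain_phantom
        voxels = volume.voxels.copy()
        voxels[voxels == L["pericyte"]] = L["macroglia"]
        bald = LabelVolume(voxels, volume.voxel_size_nm)
        with caplog.at_level("WARNING", logger="nvumorph"):
            events = detect_peg_sockets(bald, roles)
        assert events == []
        assert "pericyte" in caplog.text

    def test_missing_role_errors(self, plain_phantom):
        volume, _, _ = plain_phantom
        no_peri = RoleMap({0: "background", 2: "endothelium"})
        with pytest.raises(ValueError, match="pericyte"):
            detect_peg_sockets(volume, no_peri)


class TestDetachments:
    def test_planted_gaps_recovered_per_role(self, featured_phantom):
        spec, volume, roles, _ = featured_phantom
        claimed = detect_peg_sockets(volume, roles, return_claimed=True)[1]
        for role, expected in (("endothelium", 1), ("pericyte", 1), ("macroglia", 1)):
            events = detect_detachments(volume, roles, role, exclude_mask=claimed)
            assert len(events) == expected
            assert events[0].max_gap_nm == pytest.approx(24.0, abs=7.0)

    def test_attached_phantom_is_negative_control(self, plain_phantom):
        volume, roles, _ = plain_phantom
        for role in ("endothelium", "pericyte", "macroglia"):
            assert detect_detachments(volume, roles, role) == []

    def test_narrow_gap_below_width_threshold_excluded(self):
        spec = small_spec(
            n_slices=16,
            detachments=(small_detachment("endothelium", 8, 0.5, gap_nm=6.0),),
        )
        volume, roles, _ = generate_phantom(spec)
        params = DetectorParams(min_gap_width_nm=12.0)
        assert detect_detachments(volume, roles, "endothelium", params) == []
        # the same gap passes with a permissive threshold
        lax = DetectorParams(min_gap_width_nm=5.0)
        assert len(detect_detachments(volume, roles, "endothelium", lax)) == 1

    def test_invalid_target_role(self, plain_phantom):
        volume, roles, _ = plain_phantom
        with pytest.raises(ValueError):
            detect_detachments(volume, roles, "lumen")


class TestTubules:
    def test_opening_classes_recovered(self, featured_phantom):
        spec, volume, roles, _ = featured_phantom
        events = detect_tubules(volume, roles)
        classes = sorted(e.opening_class for e in events)
        assert classes == ["abluminal", "closed", "luminal"]

    def test_transendothelial_detected_when_planted(self):
        spec = small_spec(
            n_slices=16,
            tubules=(small_tubule(8, 1.5, opening="transendothelial"),),
        )
        volume, roles, _ = generate_phantom(spec)
        events = detect_tubules(volume, roles)
        assert [e.opening_class for e in events] == ["transendothelial"]

    def test_tiny_component_below_min_voxels_excluded(self):
        voxels, roles = toy_slab()
        voxels[1, 17, 5:7] = L["tubule"]  # 2 voxels, interior
        volume = LabelVolume(voxels)
        assert detect_tubules(volume, roles, DetectorParams(min_voxels=4)) == []
        events = detect_tubules(volume, roles, DetectorParams(min_voxels=1, min_z_slices=1))
        assert [e.opening_class for e in events] == ["closed"]

    def test_luminal_abluminal_swap_under_surface_relabel(self):
        spec = small_spec(
            n_slices=20,
            tubules=(
                small_tubule(5, 1.2, opening="luminal"),
                small_tubule(10, 2.2, opening="abluminal"),
                small_tubule(15, -2.2, opening="closed"),
            ),
        )
        volume, roles, _ = generate_phantom(spec)
        events = detect_tubules(volume, roles)
        base = sorted(e.opening_class for e in events)
        assert base == ["abluminal", "closed", "luminal"]
        # relabel lumen <-> BM: luminal and abluminal swap, closed fixed
        swapped_entries = dict(roles.entries)
        lum = [k for k, v in roles.entries.items() if v == "lumen"][0]
        bm = [k for k, v in roles.entries.items() if v == "basement_membrane"][0]
        swapped_entries[lum] = "basement_membrane"
        swapped_entries[bm] = "lumen"
        swapped = RoleMap(swapped_entries)
        flipped = detect_tubules(volume, swapped)
        assert sorted(e.opening_class for e in flipped) == ["abluminal", "closed", "luminal"]
        by_z = {e.z_start: e.opening_class for e in events}
        by_z_flipped = {e.z_start: e.opening_class for e in flipped}
        swap = {"luminal": "abluminal", "abluminal": "luminal", "closed": "closed"}
        assert {z: swap[c] for z, c in by_z.items()} == by_z_flipped


class TestFrequencies:
    @pytest.mark.parametrize(
        "count,n_slices,dz,expected",
        [(6, 300, 100.0, 2.0), (0, 300, 100.0, 0.0), (9, 130, 100.0, 9 * 10_000 / 13_000)],
    )
    def test_per_10um_arithmetic(self, count, n_slices, dz, expected):
        assert frequency_per_10um(count, n_slices, dz) == pytest.approx(expected)

    def test_zero_slices_rejected(self):
        with pytest.raises(ValueError):
            frequency_per_10um(1, 0, 100.0)


class TestSummarize:
    def test_manifest_recovered_exactly(self, featured_phantom):
        spec, volume, roles, gt = featured_phantom
        metrics = summarize_capillary(volume, roles)
        assert metrics.counts == gt.counts
        for key in gt.counts:
            assert metrics.frequency_per_10um[key] == pytest.approx(
                gt.expected_frequency_per_10um[key]
            )

    def test_no_lucent_voxel_double_counted(self, featured_phantom):
        # the detached peg's socket shell must not surface as an
        # endothelial detachment: exactly one endothelial event remains
        spec, volume, roles, gt = featured_phantom
        metrics = summarize_capillary(volume, roles)
        assert metrics.counts["detachment_endothelium"] == 1

    def test_rerun_is_deterministic(self, featured_phantom):
        spec, volume, roles, _ = featured_phantom
        m1 = summarize_capillary(volume, roles)
        m2 = summarize_capillary(volume, roles)
        assert m1.counts == m2.counts
        assert [e.centroid for e in m1.events] == [e.centroid for e in m2.events]

    def test_z_concatenation_doubles_counts_keeps_frequency(self):
        spec = small_spec(
            n_slices=24,
            pegs=(small_peg(12, 0.4),),
            tubules=(small_tubule(12, 2.2, opening="closed"),),
        )
        volume, roles, _ = generate_phantom(spec)
        metrics = summarize_capillary(volume, roles)
        doubled = LabelVolume(
            np.concatenate([volume.voxels, volume.voxels], axis=0), volume.voxel_size_nm
        )
        metrics2 = summarize_capillary(doubled, roles)
        for key in ("peg_socket", "tubule"):
            assert metrics2.counts[key] == 2 * metrics.counts[key]
            assert metrics2.frequency_per_10um[key] == pytest.approx(
                metrics.frequency_per_10um[key]
            )

    def test_boundary_touching_event_flagged(self):
        spec = small_spec(n_slices=24, tubules=(small_tubule(12, 2.2),))
        volume, roles, _ = generate_phantom(spec)
        # crop so the tubule touches the first slice
        cropped = LabelVolume(volume.voxels[11:], volume.voxel_size_nm)
        events = detect_tubules(cropped, roles)
        assert len(events) == 1 and events[0].at_boundary
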