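"""Job-file writing, output parsing, the vibrational check, failure routing."""

import numpy as np
import pytest

from daforge import qm_io, synthetic
from daforge.geometry import ConstraintSpec, DistanceConstraint, Geometry
from daforge.qm_io import (
    FrequencySet,
    InsufficientScan,
    JobSpec,
    ParseFailure,
    ScanResult,
    parse_freq_output,
    parse_irc_output,
    parse_scan_output,
    route_failure,
    select_pseudo_guess,
    vibrational_check,
    write_job,
)


@pytest.fixture
def geom():
    return Geometry(["C", "C", "H"], np.array([[0.0, 0, 0], [1.5, 0, 0], [2.1, 0.9, 0]]))


@pytest.fixture
def path_5_1_5():
    spec = synthetic.PathSpec(n_points_per_direction=5, step=0.8, n_atoms=3, seed=1)
    return synthetic.make_path(spec, name="fix")


class TestWriteJob:
    def test_irc_route_encodes_points_and_stepsize(self, geom, tmp_path):
        spec = JobSpec("irc", "B3LYP/6-31G(d)", geom,
                       irc_points_per_direction=60, irc_step_size=0.8)
        text = write_job(spec, tmp_path / "irc.gjf").read_text()
        assert "maxpoints=60" in text
        assert "stepsize=80" in text  # dialect: integer units of 0.01 amu^(1/2)*bohr
        assert "B3LYP/6-31G(d)" in text

    def test_constrained_scan_writes_two_frozen_distance_records(self, geom, tmp_path):
        cons = ConstraintSpec([DistanceConstraint(0, 1, 2.15), DistanceConstraint(1, 2, 2.15)])
        spec = JobSpec("constrained_scan", "PM6", geom, constraints=cons)
        text = write_job(spec, tmp_path / "scan.gjf").read_text()
        # 1-based atom indices in the job dialect
        assert "B 1 2 2.1500 F" in text
        assert "B 2 3 2.1500 F" in text

    def test_ts_job_requests_berny_and_frequency_check(self, geom, tmp_path):
        spec = JobSpec("ts_opt_qm", "B3LYP/6-31G(d)", geom)
        text = write_job(spec, tmp_path / "ts.gjf").read_text()
        assert "ts" in text and "berny" in text and "freq" in text

    def test_irc_without_step_size_rejected(self, geom):
        with pytest.raises(ValueError):
            JobSpec("irc", "PM6", geom, irc_points_per_direction=60)

    def test_empty_theory_rejected(self, geom):
        with pytest.raises(ValueError):
            JobSpec("frequency", "", geom)

    def test_geometry_round_trips_through_backend_output(self, geom, tmp_path):
        """write_job -> fixture backend output -> parser reproduces coordinates."""
        out = qm_io.write_gaussian_opt_log(geom, -1.0, tmp_path / "opt.log")
        parsed, _ = qm_io.parse_opt_output(out)
        np.testing.assert_allclose(parsed.coords, geom.coords, atol=1e-6)
        assert parsed.elements == geom.elements


class TestScanParsing:
    def test_configurations_in_scan_order(self, geom, tmp_path):
        energies = [-230.10, -230.05, -229.98]
        configs = [(geom, e) for e in energies]
        f = qm_io.write_gaussian_scan_log(configs, tmp_path / "scan.log")
        scan = parse_scan_output(f)
        assert [e for _, e in scan.configurations] == pytest.approx(energies)

    def test_sixteen_point_scan(self, geom, tmp_path):
        configs = [(geom, -230.0 + 0.001 * k) for k in range(16)]
        f = qm_io.write_gaussian_scan_log(configs, tmp_path / "scan.log")
        assert len(parse_scan_output(f)) == 16

    def test_truncated_output_raises(self, geom, tmp_path):
        f = qm_io.write_gaussian_scan_log([(geom, -1.0)], tmp_path / "scan.log")
        lines = f.read_text().splitlines()
        f.write_text("\n".join(lines[:-2]))  # drop termination trailer
        with pytest.raises(ParseFailure):
            parse_scan_output(f)

    def test_error_pattern_detected(self, geom, tmp_path):
        f = qm_io.write_gaussian_scan_log([(geom, -1.0)], tmp_path / "scan.log")
        f.write_text(f.read_text() + " Error termination via Lnk1e\n")
        with pytest.raises(ParseFailure):
            parse_scan_output(f)


class TestSelectPseudoGuess:
    def _scan(self, geom, energies):
        return ScanResult([(geom.copy(), e) for e in energies])

    def test_argmax_selected(self, geom):
        scan = self._scan(geom, [-1.0, -0.2, -0.6])
        chosen = select_pseudo_guess(scan)
        assert chosen.provenance == "guess_ts"
        # index 1 has the highest energy
        np.testing.assert_array_equal(chosen.coords, scan.configurations[1][0].coords)

    def test_monotone_scan_selects_last(self, geom):
        scan = self._scan(geom, [-3.0, -2.0, -1.0])
        scan.configurations[-1][0].coords[0, 0] = 9.0
        chosen = select_pseudo_guess(scan)
        assert chosen.coords[0, 0] == 9.0

    def test_tie_breaks_toward_later_index(self, geom):
        scan = self._scan(geom, [-1.0, -0.5, -0.8, -0.5])
        scan.configurations[3][0].coords[0, 0] = 7.0
        assert select_pseudo_guess(scan).coords[0, 0] == 7.0

    def test_single_configuration_insufficient(self, geom):
        with pytest.raises(InsufficientScan):
            select_pseudo_guess(self._scan(geom, [-1.0]))


class TestVibrationalCheck:
    @pytest.mark.parametrize(
        "freqs, verdict",
        [
            ([-512.3, 45.1, 220.7], "true_ts"),
            ([12.0, 45.1, 220.7], "minimum"),
            ([-512.3, -33.0, 220.7], "higher_order_saddle"),
            ([-0.1], "true_ts"),
            ([5.0], "minimum"),
            ([-1.0, -2.0, -3.0], "higher_order_saddle"),
        ],
    )
    def test_sign_pattern_truth_table(self, freqs, verdict):
        assert vibrational_check(FrequencySet(freqs)) == verdict

    def test_empty_frequency_set_invalid(self):
        with pytest.raises(ValueError):
            FrequencySet([])

    def test_freq_log_round_trip(self, tmp_path):
        f = qm_io.write_gaussian_freq_log([-512.3, 45.1, 220.7, 300.0], tmp_path / "f.log")
        fs = parse_freq_output(f)
        assert fs.frequencies == pytest.approx([-512.3, 45.1, 220.7, 300.0])
        assert vibrational_check(fs) == "true_ts"


class TestRouteFailure:
    def test_copy_not_move(self, tmp_path):
        src = tmp_path / "bad.log"
        src.write_text("rejected")
        dest = route_failure(src, "two imaginary modes", tmp_path / "ERROR_FILES", stage="refine")
        assert dest.exists() and src.exists()
        manifest = (tmp_path / "ERROR_FILES" / "manifest.tsv").read_text()
        assert "bad.log\trefine\ttwo imaginary modes" in manifest

    def test_name_collision_uniquified(self, tmp_path):
        src = tmp_path / "bad.log"
        src.write_text("first")
        d1 = route_failure(src, "r1", tmp_path / "ERROR_FILES")
        src.write_text("second")
        d2 = route_failure(src, "r2", tmp_path / "ERROR_FILES")
        assert d1 != d2 and d1.exists() and d2.exists()
        assert d2.read_text() == "second"

    def test_missing_source_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            route_failure(tmp_path / "absent.log", "x", tmp_path / "ERROR_FILES")


class TestIRCParsing:
    def test_two_direction_merge_strictly_increasing(self, path_5_1_5, tmp_path):
        f = qm_io.write_gaussian_irc_log(path_5_1_5, tmp_path / "irc.log")
        parsed = parse_irc_output(f)
        assert parsed.n_points == 11  # 5 + TS + 5, duplicate TS dropped
        assert np.all(np.diff(parsed.xi) > 0)
        np.testing.assert_allclose(parsed.xi, path_5_1_5.xi, atol=1e-5)
        np.testing.assert_allclose(parsed.energy, path_5_1_5.energy, atol=1e-8)
        np.testing.assert_allclose(
            parsed.coords_array(), path_5_1_5.coords_array(), atol=1e-6
        )

    def test_forces_parsed_when_present(self, path_5_1_5, tmp_path):
        f = qm_io.write_gaussian_irc_log(path_5_1_5, tmp_path / "irc.log")
        parsed = parse_irc_output(f)
        assert parsed.has_forces
        np.testing.assert_allclose(parsed.forces, path_5_1_5.forces, atol=1e-8)

    def test_missing_forces_flagged_not_fatal(self, path_5_1_5, tmp_path):
        bare = qm_io.IRCPath(
            xi=path_5_1_5.xi, energy=path_5_1_5.energy,
            geometries=path_5_1_5.geometries, forces=None,
        )
        f = qm_io.write_gaussian_irc_log(bare, tmp_path / "irc.log")
        parsed = parse_irc_output(f)
        assert parsed.has_forces is False

    def test_truncated_irc_raises(self, path_5_1_5, tmp_path):
        f = qm_io.write_gaussian_irc_log(path_5_1_5, tmp_path / "irc.log")
        text = f.read_text().splitlines()
        f.write_text("\n".join(text[: len(text) // 2]))
        with pytest.raises(ParseFailure):
            parse_irc_output(f)


class TestPlainPathFormat:
    def test_round_trip_with_forces(self, path_5_1_5, tmp_path):
        f = qm_io.write_path_file(path_5_1_5, tmp_path / "p.ircpath")
        back = qm_io.parse_path_file(f)
        np.testing.assert_allclose(back.xi, path_5_1_5.xi, atol=1e-9)
        np.testing.assert_allclose(back.energy, path_5_1_5.energy, atol=1e-11)
        np.testing.assert_allclose(back.coords_array(), path_5_1_5.coords_array(), atol=1e-8)
        np.testing.assert_allclose(back.forces, path_5_1_5.forces, atol=1e-8)
        assert back.name == path_5_1_5.name

    def test_dispatch_on_extension(self, path_5_1_5, tmp_path):
        f = qm_io.write_path_file(path_5_1_5, tmp_path / "p.ircpath")
        parsed = parse_irc_output(f)  # unified entry point
        assert parsed.n_points == path_5_1_5.n_points

    def test_truncated_plain_file_raises(self, path_5_1_5, tmp_path):
        f = qm_io.write_path_file(path_5_1_5, tmp_path / "p.ircpath")
        lines = f.read_text().splitlines()
        f.write_text("\n".join(lines[: len(lines) // 2]))
        with pytest.raises(ParseFailure):
            qm_io.parse_path_file(f)
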