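import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noesypop.distances import (
    SphericalHarmonicSpec,
    average_fast,
    average_medium,
    average_slow,
    classify_conformers,
    effective_distance,
    group_effective_distance,
    read_distance_table,
    write_distance_table,
)
from noesypop.errors import DomainError, UnclassifiedConformerError
from noesypop.geometry import ProtonGroup
from noesypop import datasets

from conftest import make_geometry, random_rotation

positive_distances = st.lists(
    st.floats(min_value=1.0, max_value=10.0), min_size=1, max_size=12
)


class TestScalarAverages:
    def test_singleton_identity(self):
        assert average_slow([3.0], 1, 1) == pytest.approx(3.0)
        assert average_medium([3.0], 1, 1) == pytest.approx(3.0)

    def test_two_point_values_against_direct_formula(self):
        assert average_slow([2.0, 4.0]) == pytest.approx(
            ((2.0 ** -6 + 4.0 ** -6) / 2) ** (-1 / 6)
        )
        assert average_slow([2.0, 4.0]) == pytest.approx(2.239, abs=5e-4)
        assert average_medium([2.0, 4.0]) == pytest.approx(
            ((2.0 ** -3 + 4.0 ** -3) / 2) ** (-1 / 3)
        )
        assert average_medium([2.0, 4.0]) == pytest.approx(2.423, abs=5e-4)

    def test_count_mismatch_and_domain_errors(self):
        with pytest.raises(DomainError):
            average_slow([2.0, 3.0], n_i=1, n_s=1)
        with pytest.raises(DomainError):
            average_slow([])
        with pytest.raises(DomainError):
            average_medium([2.0, -1.0])

    def test_tabulated_closed_set(self):
        # marker-pair distances of the four closed-type computed conformers
        assert average_slow([4.33, 4.31, 4.11, 4.11]) == pytest.approx(4.21, abs=5e-3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(positive_distances)
    def test_power_mean_ordering(self, dists):
        # short distances dominate r^-6 harder than r^-3, and both effective
        # values sit at or below the arithmetic mean
        slow, medium = average_slow(dists), average_medium(dists)
        assert slow <= medium + 1e-12
        assert slow <= np.mean(dists) + 1e-12


class TestFastModel:
    def test_static_limit_identity(self, rng):
        v = rng.normal(size=3)
        v = 2.5 * v / np.linalg.norm(v)
        assert average_fast([v]) == pytest.approx(2.5, abs=1e-12)

    def test_threefold_symmetric_vectors_match_explicit_harmonics(self):
        # independent oracle: explicit complex Y_2m formulas
        def y2(m, theta, phi):
            c, s = math.cos(theta), math.sin(theta)
            if m == 0:
                return math.sqrt(5 / (16 * math.pi)) * (3 * c ** 2 - 1)
            if abs(m) == 1:
                sign = -1.0 if m == 1 else 1.0
                return sign * math.sqrt(15 / (8 * math.pi)) * s * c * np.exp(1j * m * phi)
            return math.sqrt(15 / (32 * math.pi)) * s ** 2 * np.exp(1j * m * phi)

        r, tilt = 1.8, math.radians(70.0)
        vecs = []
        for k in range(3):
            phi = 2 * math.pi * k / 3
            vecs.append(
                r
                * np.array(
                    [
                        math.sin(tilt) * math.cos(phi),
                        math.sin(tilt) * math.sin(phi),
                        math.cos(tilt),
                    ]
                )
            )
        total = 0.0
        for m in range(-2, 3):
            s_m = np.mean(
                [
                    y2(m, math.acos(v[2] / r), math.atan2(v[1], v[0])) / r ** 3
                    for v in vecs
                ]
            )
            total += abs(s_m) ** 2
        expected = (4 * math.pi / 5 * total) ** (-1 / 6)
        got = average_fast(vecs)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got >= r - 1e-12  # orientational averaging cannot shorten r_eff

    def test_rotation_invariance_with_uniform_weights(self, rng):
        vecs = rng.normal(size=(4, 3)) * 2 + 3
        rot = random_rotation(rng)
        assert average_fast(vecs @ rot.T) == pytest.approx(average_fast(vecs), rel=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(DomainError):
            average_fast([[0.0, 0.0, 0.0]])

    def test_weights_validated(self):
        with pytest.raises(DomainError):
            SphericalHarmonicSpec(coefficients=(1, 1, -1, 1, 1))


class TestEffectiveDistance:
    def test_single_pair_is_plain_distance_for_all_models(self):
        geom = make_geometry(
            "c", [("H12a", "H", (0, 0, 0)), ("H12b", "H", (1.78, 0, 0))]
        )
        ga = ProtonGroup("H12a", ("H12a",), regime="slow")
        gb = ProtonGroup("H12b", ("H12b",), regime="slow")
        for model in ("slow", "medium", "fast"):
            avg = effective_distance(geom, ga, gb, model=model)
            assert avg.r_calc == pytest.approx(1.78, abs=1e-9)

    def test_two_by_two_group_uses_four_member_pairs(self):
        geom = make_geometry(
            "c",
            [
                ("H14", "H", (0, 0, 0)),
                ("H18", "H", (0, 4, 0)),
                ("H15", "H", (2.5, 0, 0)),
                ("H17", "H", (2.5, 4, 0)),
            ],
        )
        gi = ProtonGroup("H14/18", ("H14", "H18"), regime="slow")
        gs = ProtonGroup("H15/17", ("H15", "H17"), regime="slow")
        avg = effective_distance(geom, gi, gs)
        dists = [2.5, math.hypot(2.5, 4.0)] * 2
        assert avg.r_calc == pytest.approx(average_slow(dists, 2, 2))

    def test_dispatch_follows_faster_regime(self):
        geom = make_geometry(
            "c", [("A", "H", (0, 0, 0)), ("B", "H", (2, 0, 0)), ("C", "H", (2, 1, 0))]
        )
        gi = ProtonGroup("AB", ("A", "B"), regime="slow")
        gs = ProtonGroup("C", ("C",), regime="medium")
        assert effective_distance(geom, gi, gs).model == "medium"


class TestClassification:
    def test_explicit_echoes_input(self):
        res = classify_conformers(
            "explicit",
            open_ids=datasets.QC_OPEN,
            closed_ids=datasets.QC_CLOSED,
        )
        states = {c.conformer_id: c.state for c in res}
        assert all(states[c] == "open" for c in datasets.QC_OPEN)
        assert all(states[c] == "closed" for c in datasets.QC_CLOSED)

    def test_marker_rule_recovers_solid_state_families(self):
        table = datasets.load_solid_state_distances()
        res = classify_conformers(
            "marker_distance", marker_distances=dict(table["H12b-H14/18"])
        )
        opened = {c.conformer_id for c in res if c.state == "open"}
        assert opened == set(datasets.SOLID_OPEN)

    def test_fluorine_rule_and_dead_zone(self):
        res = classify_conformers(
            "fluorine_distance", fluorine_distances={"a": 5.0, "b": 9.5}
        )
        assert {c.conformer_id: c.state for c in res} == {"a": "closed", "b": "open"}
        with pytest.raises(UnclassifiedConformerError):
            classify_conformers("fluorine_distance", fluorine_distances={"c": 7.5})


class TestGroupAverage:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([3.44, 3.45, 3.62, 3.34, 3.61, 2.97], 3.35),
            ([1.56, 1.56, 1.56, 1.56, 1.57, 1.85, 1.58], 1.59),
        ],
    )
    def test_tabulated_group_cells(self, values, expected):
        assert round(group_effective_distance(values), 2) == expected

    def test_constant_values(self):
        assert group_effective_distance([2.2, 2.2, 2.2]) == pytest.approx(2.2)

    def test_singleton(self):
        assert group_effective_distance([4.1]) == pytest.approx(4.1)


class TestTableIo:
    def test_roundtrip(self):
        table = datasets.load_qc_distances()
        text = write_distance_table(table)
        back = read_distance_table(text)
        assert list(back.columns) == list(table.columns)
        assert np.allclose(back.to_numpy(), table.round(2).to_numpy())

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            read_distance_table("conformer,p\na,-1.0\n")
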