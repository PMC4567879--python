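import math

import numpy as np
import pytest

from trophoscale.io_formats import FoodWeb
from trophoscale.metrics import (
    UnrootedLoopError,
    degree_sds,
    fundamental_props,
    loop_fraction,
    max_similarity,
    node_class_fractions,
    omnivory_fraction,
    path_and_clustering,
    structural_properties,
    trophic_levels,
)

from _oracle import oracle_properties, random_web


def _web(links, taxa=None):
    taxa = set(taxa or ()) | {t for link in links for t in link}
    return FoodWeb("w", frozenset(taxa), frozenset(links))


class TestFundamental:
    @pytest.mark.parametrize(
        "links, expected",
        [
            ({("B", "A"), ("C", "B"), ("D", "A"), ("D", "B")}, (4, 4, 1.0, 0.25)),
            ({("A", "A")}, (1, 1, 1.0, 1.0)),
            ({("B", "A")}, (2, 1, 0.5, 0.25)),
        ],
    )
    def test_counts_and_connectance(self, links, expected):
        assert fundamental_props(_web(links)) == expected

    def test_empty_web_error(self):
        with pytest.raises(ValueError):
            fundamental_props(FoodWeb("w", frozenset(), frozenset()))


class TestNodeClasses:
    def test_worked_web(self, w1):
        top, mid, bas, can, herb = node_class_fractions(w1)
        assert (top, mid, bas, can, herb) == (0.5, 0.25, 0.25, 0.0, 0.25)

    def test_single_cannibal_is_basal_cannibal(self):
        top, mid, bas, can, herb = node_class_fractions(_web({("A", "A")}))
        assert (bas, can, top) == (1.0, 1.0, 0.0)

    def test_two_node_chain(self):
        top, mid, bas, can, herb = node_class_fractions(_web({("B", "A")}))
        assert (top, mid, bas, herb) == (0.5, 0.0, 0.5, 0.5)

    def test_partition_sums_to_one(self):
        for seed in range(30):
            taxa, links = random_web(seed)
            if not links:
                continue
            top, mid, bas, _, herb = node_class_fractions(_web(links, taxa))
            assert top + mid + bas == pytest.approx(1.0, abs=1e-12)
            assert herb <= 1.0 - bas + 1e-12


class TestTrophicLevels:
    def test_worked_web_three_conventions(self, w1):
        lv = trophic_levels(w1)
        assert lv.shortest == {"A": 1, "B": 2, "C": 3, "D": 2}
        assert lv.prey_averaged == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 3.0, "D": 2.5}
        )
        assert lv.short_weighted == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 3.0, "D": 2.25}
        )

    def test_chain_closed_form(self):
        k = 6
        links = {(f"t{i+1}", f"t{i}") for i in range(k - 1)}
        lv = trophic_levels(_web(links))
        for conv in (lv.shortest, lv.prey_averaged, lv.short_weighted):
            assert conv[f"t{k-1}"] == pytest.approx(k)

    def test_rooted_loop_linear_solve(self):
        # B and C eat each other, both eat basal A
        web = _web({("B", "C"), ("C", "B"), ("B", "A"), ("C", "A")})
        lv = trophic_levels(web)
        assert lv.prey_averaged["B"] == pytest.approx(3.0)
        assert lv.shortest["B"] == 2
        assert lv.short_weighted["B"] == pytest.approx(2.5)

    def test_unrooted_loop_raises(self):
        with pytest.raises(UnrootedLoopError):
            trophic_levels(_web({("B", "C"), ("C", "B")}))

    def test_defining_equation_residual(self):
        """Prey-averaged TL re-substitutes into its own equation."""
        from trophoscale.io_formats import adjacency_maps

        for seed in range(20):
            taxa, links = random_web(seed)
            web = _web(links, taxa)
            try:
                lv = trophic_levels(web)
            except UnrootedLoopError:
                continue
            prey, _ = adjacency_maps(web)
            for t in web.taxa:
                diet = prey[t] - {t}
                expected = (
                    1.0
                    if not diet
                    else 1.0 + np.mean([lv.prey_averaged[j] for j in diet])
                )
                assert abs(lv.prey_averaged[t] - expected) <= 1e-9


class TestOtherStructural:
    def test_omnivory(self, w1):
        assert omnivory_fraction(w1, trophic_levels(w1)) == 0.25

    def test_two_basal_prey_is_not_omnivory(self):
        web = _web({("C", "A"), ("C", "B")})
        assert omnivory_fraction(web, trophic_levels(web)) == 0.0

    def test_loop_fraction(self):
        web = _web({("B", "C"), ("C", "B"), ("B", "A"), ("C", "A")})
        assert loop_fraction(web) == pytest.approx(2 / 3)
        assert loop_fraction(_web({("B", "A"), ("C", "B")})) == 0.0
        assert loop_fraction(_web({("A", "A")})) == 0.0  # cannibalism alone

    def test_degree_sds_worked_web(self, w1):
        link_sd, gen_sd, vul_sd = degree_sds(w1)
        assert gen_sd == pytest.approx(math.sqrt(2 / 3), abs=1e-12)
        assert vul_sd == pytest.approx(math.sqrt(4 / 3), abs=1e-12)
        assert link_sd == pytest.approx(math.sqrt(1 / 6), abs=1e-12)

    def test_degree_sds_regular_ring_zero(self):
        n = 5
        links = {(f"t{(i+1)%n}", f"t{i}") for i in range(n)}
        assert degree_sds(_web(links)) == (0.0, 0.0, 0.0)

    def test_max_similarity_worked_web(self, w1):
        assert max_similarity(w1) == pytest.approx(0.375)

    def test_identical_roles_have_similarity_one(self):
        web = _web({("B1", "A"), ("B2", "A"), ("C", "B1"), ("C", "B2")})
        # B1 and B2 share everything, so both achieve max similarity 1
        assert max_similarity(web) >= 0.5  # mean includes A's and C's maxima

    def test_path_and_clustering_worked_web(self, w1):
        path, clust = path_and_clustering(w1)
        assert path == pytest.approx(4 / 3)
        assert clust == pytest.approx(7 / 18)

    def test_star_and_triangle(self):
        star = _web({("hub", f"leaf{i}") for i in range(3)})
        path, clust = path_and_clustering(star)
        assert path == pytest.approx(1.5)
        assert clust == 0.0
        # directed 3-cycle: each node sees 1 directed link among its 2
        # neighbors, so the directed clustering coefficient is 1/2
        tri = _web({("B", "A"), ("C", "B"), ("A", "C")})
        path, clust = path_and_clustering(tri)
        assert path == 1.0 and clust == 0.5


class TestComposition:
    def test_worked_web_record(self, w1):
        rec = structural_properties(w1)
        expected = {
            "Top": 0.5, "Int": 0.25, "Bas": 0.25, "Can": 0.0, "Herb": 0.25,
            "Omn": 0.25, "TL": 2.0625, "GenSD": 0.8165, "VulSD": 1.1547,
            "LinkSD": 0.4082, "MaxSim": 0.375, "Path": 1.3333, "Clust": 0.3889,
        }
        for prop, value in expected.items():
            assert getattr(rec, prop) == pytest.approx(value, abs=5e-5), prop

    def test_unrooted_loop_marks_missing_not_fatal(self):
        rec = structural_properties(_web({("B", "C"), ("C", "B")}))
        assert rec.TL is None and rec.Omn is None
        assert rec.Loop == 1.0
        assert any("basal" in e for e in rec.errors)

    def test_niche_web_smoke_no_missing(self):
        from trophoscale.niche import generate_niche_web

        rng = np.random.default_rng(5)
        rec = structural_properties(generate_niche_web(30, 0.15, rng))
        assert rec.errors == ()
        assert all(
            getattr(rec, p) is not None
            for p in ("TL", "Path", "Clust", "MaxSim", "GenSD")
        )

    def test_relabeling_invariance(self):
        taxa, links = random_web(99)
        web = _web(links, taxa)
        mapping = {t: f"Z{ord(t[1]) * 7}{t}" for t in taxa}
        relabeled = FoodWeb(
            "w2",
            frozenset(mapping[t] for t in taxa),
            frozenset((mapping[c], mapping[r]) for c, r in links),
        )
        a = structural_properties(web).to_dict()
        b = structural_properties(relabeled).to_dict()
        for key in a:
            if key in ("web_id", "scale_label"):
                continue
            if a[key] is None:
                assert b[key] is None
            else:
                assert a[key] == pytest.approx(b[key], abs=1e-12), key

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_oracle(self, seed):
        """Every property agrees with the naive reference implementation."""
        taxa, links = random_web(seed)
        if not links:
            links = {(taxa[1], taxa[0])}
        rec = structural_properties(_web(links, taxa)).to_dict()
        ref = oracle_properties(taxa, links)
        for prop, expected in ref.items():
            got = rec[prop]
            if expected is None:
                assert got is None, prop
            else:
                assert got == pytest.approx(expected, abs=1e-9), prop
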