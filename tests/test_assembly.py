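import numpy as np
import pytest

from trophoscale.assembly import (
    AssemblyConfig,
    assemble_collection,
    extract_local_web,
    filter_by_richness,
)
from trophoscale.io_formats import FoodWeb, SpeciesCatalog, WebCollection


def _web(links, taxa=None, web_id="mw"):
    taxa = set(taxa or ()) | {t for link in links for t in link}
    return FoodWeb(web_id, frozenset(taxa), frozenset(links))


def _cat(taxa, sample_id="u1", scale="quadrat", area=0.25):
    return SpeciesCatalog(sample_id, scale, area, frozenset(taxa))


CHAIN = _web({("B", "A"), ("C", "B")})  # C eats B eats A


class TestExtractLocalWeb:
    def test_non_cooccurring_chain_ends_drop_to_empty(self):
        """A and C share no direct link, so both are dropped as unlinked."""
        web = extract_local_web(CHAIN, _cat({"A", "C"}), AssemblyConfig())
        assert web.is_empty

    def test_induced_subgraph(self):
        web = extract_local_web(CHAIN, _cat({"A", "B"}), AssemblyConfig())
        assert web.S == 2 and web.links == frozenset([("B", "A")])

    def test_ubiquitous_injection_after_drop(self):
        """Detritus feeders keep their detrital link only via injection."""
        mw = _web({("B", "D"), ("C", "B")})
        cfg = AssemblyConfig(ubiquitous_taxa=frozenset("D"))
        web = extract_local_web(mw, _cat({"B", "C"}), cfg)
        assert web.taxa == frozenset("BCD")
        assert web.links == frozenset([("C", "B"), ("B", "D")])

    def test_taxon_linked_only_to_ubiquitous_drops_before_injection(self):
        """Order of operations: induce -> drop -> inject."""
        mw = _web({("B", "D"), ("C", "A")})
        cfg = AssemblyConfig(ubiquitous_taxa=frozenset("D"))
        web = extract_local_web(mw, _cat({"B"}), cfg)
        # B's only link is to ubiquitous D, so B is dropped first; the web
        # then holds just the injected D
        assert web.taxa == frozenset("D") and web.L == 0

    def test_unmatched_taxa_warn_not_error(self, caplog):
        with caplog.at_level("WARNING"):
            web = extract_local_web(
                CHAIN, _cat({"A", "B", "ghost"}), AssemblyConfig()
            )
        assert web.S == 2
        assert any("ghost" in r.message for r in caplog.records)

    def test_carries_catalog_scale_and_area(self):
        web = extract_local_web(
            CHAIN, _cat({"A", "B"}, scale="site", area=0.23e6), AssemblyConfig()
        )
        assert web.scale_label == "site" and web.area_m2 == 0.23e6

    def test_empty_metaweb_error(self):
        empty = FoodWeb("mw", frozenset(), frozenset())
        with pytest.raises(ValueError, match="empty metaweb"):
            extract_local_web(empty, _cat({"A"}), AssemblyConfig())

    def test_no_link_invention_and_monotonicity(self):
        """Output links are metaweb links; enlarging the catalog never
        removes a link present in the smaller catalog's web."""
        rng = np.random.default_rng(7)
        taxa = [f"t{i}" for i in range(20)]
        links = {
            (taxa[i], taxa[j])
            for i in range(20)
            for j in range(20)
            if i != j and rng.random() < 0.15
        }
        mw = _web(links, taxa)
        cfg = AssemblyConfig()
        for _ in range(20):
            small = set(rng.choice(taxa, size=8, replace=False))
            large = small | set(rng.choice(taxa, size=6, replace=False))
            ws = extract_local_web(mw, _cat(small), cfg)
            wl = extract_local_web(mw, _cat(large), cfg)
            assert ws.links <= mw.links and wl.links <= mw.links
            assert ws.links <= wl.links


class TestCollectionOps:
    def test_one_web_per_catalog_with_manifest(self):
        cats = [_cat({"A", "B"}, f"q{i}") for i in range(3)]
        coll = assemble_collection(CHAIN, cats, AssemblyConfig())
        assert len(coll) == 3 and len(coll.manifest) == 3
        assert list(coll.manifest["web_id"]) == ["q0", "q1", "q2"]

    def test_unmatched_only_catalog_flagged_empty(self):
        cats = [_cat({"X", "Y"}, "q0"), _cat({"A", "B"}, "q1")]
        coll = assemble_collection(CHAIN, cats, AssemblyConfig())
        assert list(coll.manifest["empty"]) == [True, False]

    def test_deterministic(self):
        cats = [_cat({"A", "B", "C"}, "q0")]
        a = assemble_collection(CHAIN, cats, AssemblyConfig())
        b = assemble_collection(CHAIN, cats, AssemblyConfig())
        assert a.webs[0].links == b.webs[0].links

    def test_filter_threshold_is_inclusive_on_trophic_counts(self):
        # chains of distinct lengths: trophic S equals taxonomic S
        webs = []
        for n in (9, 10, 11):
            taxa = [f"t{i}" for i in range(n)]
            links = {(taxa[i + 1], taxa[i]) for i in range(n - 1)}
            webs.append(
                FoodWeb(f"w{n}", frozenset(taxa), frozenset(links), "quadrat", 0.25)
            )
        filtered, report = filter_by_richness(WebCollection(webs=webs), 10)
        assert {w.web_id for w in filtered.webs} == {"w10", "w11"}
        assert report.loc[0, "retained"] == 2 and report.loc[0, "excluded"] == 1

    def test_filter_counts_trophic_not_taxonomic_species(self):
        # 12 taxonomic herbivores sharing one plant collapse to 2 trophic
        # species, so the web falls below a threshold of 3
        taxa = {"plant"} | {f"h{i}" for i in range(12)}
        links = {(f"h{i}", "plant") for i in range(12)}
        web = FoodWeb("w", frozenset(taxa), frozenset(links), "quadrat", 0.25)
        filtered, _ = filter_by_richness(WebCollection(webs=[web]), 3)
        assert len(filtered) == 0

    def test_threshold_one_retains_all_nonempty(self):
        web = FoodWeb("w", frozenset("AB"), frozenset([("B", "A")]), "quadrat", 0.25)
        filtered, _ = filter_by_richness(WebCollection(webs=[web]), 1)
        assert len(filtered) == 1
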