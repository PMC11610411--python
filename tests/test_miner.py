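"""Fetcher politeness, page parsing, checkpointing and crawl resumption."""

import pytest

from conftest import CrawlInterrupted, KillingFetcher, MockClock

from floramine import miner
from floramine.miner import (
    CheckpointError,
    CrawlCheckpoint,
    Crawler,
    PageFetcher,
    PageResolutionError,
    ParseError,
    RateLimitPolicy,
    TaxonURI,
    load_checkpoint,
    parse_family_page,
    parse_genus_page,
    parse_species_page,
    save_checkpoint,
)
from floramine.synthetic import CountRange, SyntheticFloraSpec, generate_flora, render_site


class TestRateLimit:
    def _fetch_n(self, demo_site, n, policy):
        clock = MockClock()
        fetcher = PageFetcher(demo_site["dir"], policy, clock=clock)
        for _ in range(n):
            fetcher.fetch("index.html")
        return clock

    def test_no_pause_below_threshold(self, demo_site):
        clock = self._fetch_n(demo_site, 499, RateLimitPolicy())
        assert clock.sleeps == []

    def test_default_policy_pauses_300s_at_500th_request(self, demo_site):
        clock = self._fetch_n(demo_site, 500, RateLimitPolicy())
        assert clock.sleeps == [300.0]

    def test_small_policy_pauses_on_every_multiple(self, demo_site):
        clock = self._fetch_n(demo_site, 5, RateLimitPolicy(2, 10.0))
        assert clock.sleeps == [10.0, 10.0]

    @pytest.mark.parametrize("n,per_pause", [(7, 3), (12, 4), (9, 1)])
    def test_total_pause_time_is_floor_rule(self, demo_site, n, per_pause):
        clock = self._fetch_n(demo_site, n, RateLimitPolicy(per_pause, 5.0))
        assert clock.total == (n // per_pause) * 5.0

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            RateLimitPolicy(0)


class TestFetcher:
    def test_missing_local_file_is_resolution_error(self, demo_site):
        fetcher = PageFetcher(demo_site["dir"], clock=MockClock())
        with pytest.raises(PageResolutionError):
            fetcher.fetch("taxon/nope.html")

    def test_transient_failures_retry_with_doubling_backoff(self, demo_site):
        clock = MockClock()

        class Flaky(PageFetcher):
            fails = 2

            def _load_once(self, rel):
                if self.fails:
                    self.fails -= 1
                    raise OSError("boom")
                return super()._load_once(rel)

        fetcher = Flaky(demo_site["dir"], clock=clock, backoff_seconds=1.0)
        fetcher.fetch("index.html")
        assert clock.sleeps == [1.0, 2.0]  # doubling backoff
        assert fetcher.request_count == 3  # retries count as requests

    def test_permanent_failure_raises_after_three_retries(self, demo_site):
        class Dead(PageFetcher):
            def _load_once(self, rel):
                raise OSError("down")

        fetcher = Dead(demo_site["dir"], clock=MockClock())
        with pytest.raises(miner.FetchError):
            fetcher.fetch("index.html")
        assert fetcher.request_count == 4  # initial attempt + 3 retries


class TestParsers:
    def test_family_page_lists_genera_in_order(self, demo_site):
        html = (demo_site["dir"] / "taxon" / "10000001-1.html").read_text()
        family, genera = parse_family_page(html)
        assert family == "Demoaceae"
        assert [g.record_id for g in genera] == ["20000001-1", "20000002-1"]
        assert all(g.rank == "genus" and g.family == "Demoaceae" for g in genera)

    def test_genus_page_counts_species_links(self, demo_site):
        html = (demo_site["dir"] / "taxon" / "20000001-1.html").read_text()
        summary, species = parse_genus_page(html)
        assert summary.genus == "Alpha" and summary.species_count == 3
        assert len(species) == 3

    def test_genus_without_species_counts_zero(self):
        from floramine.model import GenusSummary
        from floramine.synthetic import _genus_page

        empty = GenusSummary("Vacua", "L.", "Gen. 1: 1 (1800)", 0,
                             "20000009-1", "taxon/20000009-1.html", "Demoaceae")
        summary, species = parse_genus_page(_genus_page(empty, []))
        assert summary.species_count == 0 and species == []

    def test_species_page_with_distribution(self, demo_site):
        html = (demo_site["dir"] / "taxon" / "30000004-1.html").read_text()
        sp = parse_species_page(html)
        assert sp.distribution.native_botanical == {"Borneo", "Peru"}
        assert sp.distribution.introduced_botanical == {"Madagascar"}
        assert sp.accepted.year == 1900

    def test_missing_distribution_section_means_unknown(self, demo_site):
        html = (demo_site["dir"] / "taxon" / "30000003-1.html").read_text()
        sp = parse_species_page(html)
        assert sp.distribution.is_unknown

    def test_mangled_page_raises_parse_error_naming_selector(self):
        with pytest.raises(ParseError, match="genus-list"):
            parse_family_page(
                '<html><head><meta name="site-dialect" content="synthflora-1">'
                '</head><body><h1 class="taxon-name" data-rank="family">X</h1></body></html>'
            )

    def test_unknown_dialect_is_an_explicit_error(self):
        with pytest.raises(ParseError, match="dialect"):
            parse_family_page(
                '<html><head><meta name="site-dialect" content="powo-2099"></head>'
                "<body></body></html>"
            )

    def test_all_demo_pages_roundtrip_to_ground_truth(self, demo_site):
        flora = demo_site["flora"]
        for sp in flora.species:
            html = (demo_site["dir"] / sp.accepted.uri).read_text()
            assert parse_species_page(html) == sp


class TestCheckpoint:
    def _cp(self):
        t = TaxonURI("Demoaceae", "family", "1-1", "taxon/1-1.html")
        return CrawlCheckpoint(completed=[t], pending=[], request_count=3,
                               failures=[(t, "boom")])

    def test_save_load_roundtrip(self, tmp_path):
        path = tmp_path / "cp.jsonl"
        cp = self._cp()
        save_checkpoint(cp, path)
        back = load_checkpoint(path)
        assert back.completed == cp.completed
        assert back.request_count == 3
        assert back.failures == cp.failures

    def test_corrupt_checkpoint_refuses_to_load(self, tmp_path):
        path = tmp_path / "cp.jsonl"
        save_checkpoint(self._cp(), path)
        body = path.read_text().replace("Demoaceae", "Tamperaceae")
        path.write_text(body)
        with pytest.raises(CheckpointError, match="hash"):
            load_checkpoint(path)

    def test_truncated_checkpoint_refuses_to_load(self, tmp_path):
        path = tmp_path / "cp.jsonl"
        path.write_text("{}\n")
        with pytest.raises(CheckpointError):
            load_checkpoint(path)


class TestCrawl:
    def test_fresh_crawl_of_demo_yields_all_species(self, demo_site, demo_roots, tmp_path):
        fetcher = PageFetcher(demo_site["dir"], clock=MockClock())
        crawler = Crawler(fetcher, tmp_path / "cp.jsonl")
        records = list(crawler.run(demo_roots))
        assert records == demo_site["flora"].species
        assert crawler.checkpoint.failures == []

    def test_interrupt_and_resume_fetches_only_the_rest(self, demo_site, demo_roots, tmp_path):
        cp_path = tmp_path / "cp.jsonl"
        killer = KillingFetcher(demo_site["dir"], kill_after=5, clock=MockClock())
        got = []
        with pytest.raises(CrawlInterrupted):
            for rec in Crawler(killer, cp_path).run(demo_roots):
                got.append(rec)
        resumer = PageFetcher(demo_site["dir"], clock=MockClock())
        got += list(Crawler(resumer, cp_path).run(demo_roots))
        assert got == demo_site["flora"].species
        combined = killer.log + resumer.log
        assert len(combined) == len(set(combined))  # zero duplicate fetches

    def test_failed_page_is_recorded_and_skipped(self, demo_site, demo_roots, tmp_path):
        class Dead404(PageFetcher):
            def _load_once(self, rel):
                if "30000002-1" in rel:
                    raise PageResolutionError(f"no such page: {rel}")
                return super()._load_once(rel)

        crawler = Crawler(Dead404(demo_site["dir"], clock=MockClock()), tmp_path / "cp.jsonl")
        records = list(crawler.run(demo_roots))
        assert [r.binomial for r in records] == ["Alpha unus", "Alpha tres", "Beta quattuor"]
        assert [t.uri for t, _ in crawler.checkpoint.failures] == ["taxon/30000002-1.html"]

    def test_randomized_floras_roundtrip_exactly(self, tmp_path):
        spec = SyntheticFloraSpec(
            n_families=2,
            genera_per_family=CountRange(2, 4),
            species_per_genus=CountRange(2, 8),
            seed=42,
        )
        flora = generate_flora(spec)
        site = tmp_path / "site"
        render_site(flora, site)
        fetcher = PageFetcher(site, clock=MockClock())
        roots = miner.parse_index_page(fetcher.fetch("index.html"))
        records = list(Crawler(fetcher, tmp_path / "cp.jsonl").run(roots))
        key = lambda s: s.accepted.record_id
        assert sorted(records, key=key) == sorted(flora.species, key=key)
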