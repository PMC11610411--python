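import json

import pytest

from floramine import miner
from floramine.geography import load_mapping
from floramine.queries import Checklist
from floramine.synthetic import demo_flora, render_site


class MockClock:
    """Records requested sleeps instead of sleeping."""

    def __init__(self):
        self.sleeps: list[float] = []

    def sleep(self, seconds: float) -> None:
        self.sleeps.append(seconds)

    @property
    def total(self) -> float:
        return sum(self.sleeps)


class CrawlInterrupted(Exception):
    """Simulated mid-crawl crash."""


class KillingFetcher(miner.PageFetcher):
    """Fetcher that dies after a set number of successful page loads."""

    def __init__(self, base, kill_after: int, **kwargs):
        super().__init__(base, **kwargs)
        self.kill_after = kill_after

    def fetch(self, uri):
        if len(self.log) >= self.kill_after:
            raise CrawlInterrupted(f"killed after {self.kill_after} fetches")
        return super().fetch(uri)


@pytest.fixture(scope="session")
def mapping():
    return load_mapping()


@pytest.fixture()
def flora():
    return demo_flora()


@pytest.fixture(scope="session")
def demo_site(tmp_path_factory):
    """The demonstration flora rendered as a static site, once per session."""
    site = tmp_path_factory.mktemp("demo_site")
    f = demo_flora()
    manifest = render_site(f, site)
    return {"flora": f, "dir": site, "manifest": manifest}


@pytest.fixture()
def demo_roots(demo_site):
    fetcher = miner.PageFetcher(demo_site["dir"])
    return miner.parse_index_page(fetcher.fetch("index.html"))


@pytest.fixture()
def demo_checklist(flora, mapping):
    return Checklist(flora.species, mapping, genus_index=flora.genus_index)


def _square(x0, y0, size=8):
    return [[
        [x0, y0], [x0 + size, y0], [x0 + size, y0 + size], [x0, y0 + size], [x0, y0],
    ]]


@pytest.fixture()
def toy_geojson(tmp_path):
    """Five schematic country squares matching the demo flora's countries."""
    names = ["Brunei", "Indonesia", "Malaysia", "Peru", "Madagascar"]
    features = [
        {
            "type": "Feature",
            "properties": {"region_name": name},
            "geometry": {"type": "Polygon", "coordinates": _square(10 * i, 0)},
        }
        for i, name in enumerate(names)
    ]
    path = tmp_path / "toy_world.geojson"
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path
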