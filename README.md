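# floramine

Mining, conversion and visualisation of plant checklists in the style of
Kew's Plants of the World Online (POWO), which serves the World Checklist
of Vascular Plants (WCVP) as per-taxon webpages.

**Who it is for.** Botanists, biogeographers and conservation scientists
who need species lists with synonymy and distribution for a family,
genus or country — and publication-ready richness maps and
species-discovery graphics — without hand-scraping taxon pages or writing
ad-hoc joins between taxonomic and geographic tables.

**What it does.**

* **Mining** — a resumable, rate-limited crawler walks family → genus →
  species pages (live base URL or a local directory) and parses each into
  a typed record: accepted name with authorship and protologue citation,
  homotypic/heterotypic synonyms, native and introduced distribution.
  Long crawls pause 300 s after every 500th request by default, and a
  checkpoint written after every taxon means an interrupted search resumes
  from the most recently retrieved taxon with no re-fetching.
* **Geography** — POWO distributions come as TDWG level-3 *botanical
  countries* (e.g. Borneo), which often do not coincide with political
  countries. A bundled many-to-many mapping converts them
  (Borneo → Brunei, Indonesia, Malaysia), so every list carries both
  levels.
* **Queries** — family species counts, genus lists with per-genus counts,
  species lists (optionally constrained to countries of native
  occurrence), targeted distribution lookups for a designated species
  list, megadiverse genera (default: strictly more than 500 species,
  Frodin's cutoff for large plant genera), and topmost species-rich
  genera with tie-aware top-N. All export to CSV.
* **Visualisation** — species-richness choropleths per country or
  botanical country on user-supplied GeoJSON polygons, and
  species-discovery accumulation curves under two date bases: the
  publication year of the currently *accepted* name, versus the year of
  the *basionym* (the earliest homotypic name), which dates the actual
  discovery and discounts purely nomenclatural recombination. Since a
  basionym cannot postdate its recombination, the basionym-basis curve
  always runs on or above the accepted-basis curve.
* **Synthetic floras** — a seeded generator produces ground-truth
  checklists with controlled statistics and renders them as a static
  taxon site, so the entire crawl → parse → analyse pipeline is testable
  offline and byte-reproducibly.

## Worked example

```python
import pathlib, tempfile
from floramine import demo_flora, render_site
from floramine import miner, queries, viz

# a tiny fixed flora (1 family, 2 genera, 4 species), rendered as a site
flora = demo_flora()
site = pathlib.Path(tempfile.mkdtemp()) / "site"
render_site(flora, site)

# crawl it back
fetcher = miner.PageFetcher(site)
roots = miner.parse_index_page(fetcher.fetch("index.html"))
crawler = miner.Crawler(fetcher, site / "crawl.jsonl")
records = list(crawler.run(roots))
print(f"mined {len(records)} species from {len(fetcher.log)} pages")

checklist = queries.Checklist(records, genus_index=crawler.genus_summaries)
for g in queries.genus_list(checklist):
    print(f"{g.genus} {g.authorship}: {g.species_count} accepted species")

peru = queries.species_list(checklist, queries.QueryFilter(countries=("Peru",)))
print("native in Peru:", ", ".join(r.binomial for r in peru))

table = viz.richness_table(checklist.annotated, viz.COUNTRY_LEVEL)
print("country richness:", dict(sorted(table.counts.items())),
      "| unmapped species:", table.unknown_count)

acc = viz.accumulation_series(records, viz.ACCEPTED_BASIS)
bas = viz.accumulation_series(records, viz.BASIONYM_BASIS)
print("accepted-date curve:", acc.points)
print("basionym-date curve:", bas.points)
```

This prints:

```
mined 4 species from 8 pages
Alpha L.: 3 accepted species
Beta Sm.: 1 accepted species
native in Peru: Alpha duo, Beta quattuor
country richness: {'Brunei': 2, 'Indonesia': 2, 'Malaysia': 2, 'Peru': 2} | unmapped species: 1
accepted-date curve: ((1753, 1), (1820, 2), (1850, 3), (1900, 4))
basionym-date curve: ((1753, 1), (1801, 2), (1820, 3), (1900, 4))
```

Reading the output: *Alpha unus* is native to Borneo, so it counts once
in each of Brunei, Indonesia and Malaysia at the country level; *Alpha
tres* has no distribution information, so it is reported as the one
"unmapped" species rather than silently dropped. On the discovery
curves, *Alpha duo* (accepted name published 1850) has a homotypic
synonym from 1801 — its basionym — so the basionym-basis curve reaches 2
species in 1801 while the accepted-basis curve waits until 1850.

## Command line

```sh
floramine synth --families 2 --seed 3 --out demo_site     # synthetic site + ground truth
floramine mine --site-dir demo_site --out mined --checkpoint crawl.jsonl
floramine genera  --checklist mined/checklist.csv --out results
floramine species --checklist mined/checklist.csv --country Peru --out results
floramine megagen --checklist mined/checklist.csv --threshold 5 --out results
floramine map   --checklist mined/checklist.csv --geojson world.geojson --out results
floramine graph --checklist mined/checklist.csv --group-by family --out results
```

`mine` also accepts `--base-url`, `--requests-per-pause` and
`--pause-seconds` for live crawls.

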