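"""High-level pipeline stages chaining fixtures to reports.

Each function is a thin composition of the module-level operations so the
command line, the analysis drivers and the acceptance checks all run the
same code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .config import RunConfig
from .fixtures import KaryotypeFixture, load_species_fixture
from .ideogram import plot_ideogram
from .karyotype import KaryotypeResult, analyze_karyotype, pair_homologs
from .measure import measure_spread
from .measurements import MeasurementTable
from .profiles import SignalProfile, encode_signal_profile, profile_from_fixture
from .render import MetaphaseImage, RenderParams, render_metaphase_image
from .report import write_report
from .segmentation import SegParams, segment_chromosomes
from .signals import DetectedSignals, SpotParams, detect_signals
from .simulate import generate_measurement_table

log = logging.getLogger("karyofish")


@dataclass
class SpeciesRun:
    """Everything computed for one species in a pipeline run."""

    fixture: KaryotypeFixture
    table: MeasurementTable                  # fixture-generated
    image: MetaphaseImage | None = None
    measured: MeasurementTable | None = None  # image-measured
    detected: DetectedSignals | None = None
    karyotype: KaryotypeResult | None = None
    profile: SignalProfile | None = None


def simulate_species(
    species: str,
    seed: int = 1,
    noise_cv: float = 0.0,
    render: bool = True,
    render_params: RenderParams | None = None,
) -> SpeciesRun:
    """Fixture -> measurement table -> (optionally) rendered spread."""
    fixture = load_species_fixture(species)
    table = generate_measurement_table(fixture, seed=seed, noise_cv=noise_cv)
    image = None
    if render:
        image = render_metaphase_image(
            table, fixture.signal_pairs, seed=seed, params=render_params
        )
    return SpeciesRun(fixture=fixture, table=table, image=image)


def measure_species(
    run: SpeciesRun,
    seg_params: SegParams | None = None,
    spot_params: SpotParams | None = None,
) -> SpeciesRun:
    """Segment, measure and detect signals on the run's rendered spread."""
    if run.image is None:
        raise ValueError("no rendered image to measure")
    masks = segment_chromosomes(run.image, seg_params)
    measured = measure_spread(masks, run.image.pixel_size_um,
                              species_id=run.fixture.species_id)
    detected = detect_signals(run.image, masks, spot_params)
    measured = pair_homologs(measured, detected.sites)
    run.measured = measured
    run.detected = detected
    return run


def analyze_species(run: SpeciesRun, use_measured: bool = False) -> SpeciesRun:
    """Karyotype analytics and signal profile for one species."""
    if use_measured:
        if run.measured is None or run.detected is None:
            raise ValueError("measure the rendered spread first")
        table = run.measured
        run.profile = encode_signal_profile(table, run.detected.sites)
    else:
        table = run.table
        run.profile = profile_from_fixture(run.fixture)
    run.karyotype = analyze_karyotype(table, ploidy=run.fixture.ploidy)
    return run


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 render: bool = True) -> dict[str, Path]:
    """simulate -> measure -> analyze -> cluster -> report for all species."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runs: list[SpeciesRun] = []
    for i, species in enumerate(config.species):
        seed = config.seed + i
        log.info("simulating %s (seed %d, noise_cv %g)",
                 species, seed, config.noise_cv)
        run = simulate_species(
            species, seed=seed, noise_cv=config.noise_cv, render=render,
            render_params=RenderParams(pixel_size_um=config.pixel_size_um),
        )
        if render:
            run = measure_species(run)
            log.info("%s: %d masks segmented", species, len(run.measured))
        run = analyze_species(run)
        run.table.write_tsv(out / f"table_{run.fixture.species_id}.tsv")
        if run.measured is not None:
            run.measured.write_tsv(
                out / f"measured_{run.fixture.species_id}.tsv")
        plot_ideogram(run.table, run.fixture.signal_pairs and _fixture_sites(run),
                      out / f"ideogram_{run.fixture.species_id}.svg")
        runs.append(run)

    sites_by_species = {
        r.fixture.species_id: r.detected.sites
        for r in runs if r.detected is not None
    }
    return write_report(
        [r.karyotype for r in runs],
        out,
        profiles=[r.profile for r in runs],
        sites_by_species=sites_by_species,
        config=config,
        linkage=config.linkage,
        weights=config.weights(),
    )


def _fixture_sites(run: SpeciesRun):
    """Ideogram-friendly pseudo-sites from the fixture assignments."""
    from .signals import SignalSite

    sites = []
    pair_rows: dict[int, list[str]] = {}
    singles: dict[int, int] = {}
    for row in run.table:
        pair_rows.setdefault(row.pair_index, []).append(row.chromosome_id)
    for sig in run.fixture.signal_pairs:
        chrom_ids = pair_rows.get(sig.pair_index, [])
        if sig.zygosity == "both-homologs":
            targets = chrom_ids
        else:  # deal one-homolog assignments to successive homologs
            k = singles.get(sig.pair_index, 0)
            singles[sig.pair_index] = k + 1
            targets = chrom_ids[k % len(chrom_ids):][:1] if chrom_ids else []
        for cid in targets:
            sites.append(SignalSite(
                chromosome_id=cid, channel=sig.channel, arm=sig.arm,
                position_fraction=sig.position_fraction,
                intensity=sig.intensity, raw_intensity=0.0,
                row=0.0, col=0.0,
            ))
    return sites
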