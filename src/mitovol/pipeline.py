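"""End-to-end pipeline: phantom/ingest -> segment -> measure -> identify
-> density, with a run manifest echoing every parameter."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import identity_density, morphometry, phantom, segment3d, volio

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, echoed verbatim into the manifest.

    Defaults are the published analysis settings: 5x5x1 average binning,
    26-neighbourhood, 4-step marker extension, 10 width samples per
    chromosome, 195 bp per nucleosome.
    """

    output_dir: str
    input_stack: str | None = None  # multipage TIFF; mutually exclusive with phantom_config
    phantom_config: str | None = None  # PhantomSpec YAML
    spacing: tuple[float, float, float] = phantom.DEFAULT_SPACING
    segmentation: segment3d.SegmentationConfig = field(default_factory=segment3d.SegmentationConfig)
    n_width: int = 10
    end_exclusion_fraction: float = 0.1
    centromere_exclusion_fraction: float = 0.1
    karyotype_csv: str | None = None
    total_dna_mb: float | None = None  # overrides the karyotype total for densities
    bp_per_nucleosome: float = 195.0
    nucleosome_free_fraction: float = 0.0
    occupied_volume_nm3: float | None = None
    seed: int = 0

    def manifest(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["spacing"] = list(self.spacing)
        doc["segmentation"]["bin_factors"] = list(self.segmentation.bin_factors)
        return doc


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages, writing labels, measurements.csv, report.json
    and manifest.json into ``config.output_dir``.

    Fails loudly: any stage failure raises :class:`PipelineError` naming
    the stage, after writing a FAILED marker next to any partial output.
    Output is deterministic given the config (incl. seed).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        if (config.input_stack is None) == (config.phantom_config is None):
            raise ValueError("exactly one of input_stack / phantom_config must be given")
        if config.phantom_config is not None:
            spec = phantom.PhantomSpec.from_yaml(config.phantom_config)
            spec.seed = config.seed
            vol, truth_labels, truth = phantom.generate_phantom(spec)
            volio.write_stack(vol, out / "stack.tif")
            volio.write_stack(truth_labels, out / "truth_labels.tif")
            total_mb = float(truth.dna_content_mb.sum())
        else:
            vol = volio.read_stack(config.input_stack, config.spacing)
            total_mb = float("nan")
        if config.total_dna_mb is not None:
            total_mb = config.total_dna_mb

        stage = "segment"
        labels, seg_info = segment3d.segment(vol, config.segmentation)
        volio.write_stack(labels, out / "labels.tif")

        stage = "measure"
        objects = morphometry.measure_all(
            labels,
            n_width=config.n_width,
            end_exclusion_fraction=config.end_exclusion_fraction,
            centromere_exclusion_fraction=config.centromere_exclusion_fraction,
        )

        stage = "identify"
        karyotype = None
        if config.karyotype_csv is not None:
            karyotype = identity_density.KaryotypeTable.from_csv(config.karyotype_csv)
            identity_density.assign_identities(objects, karyotype)
        volio.write_measurements(objects, out / "measurements.csv")

        stage = "density"
        total_volume = sum(o.volume for o in objects if o.volume)
        report: dict = {"total_volume_um3": total_volume, "n_objects": len(objects), **seg_info}
        if karyotype is not None and config.total_dna_mb is None:
            total_mb = karyotype.total_content_mb
        if total_mb == total_mb and total_mb > 0 and total_volume > 0:  # not NaN
            density = identity_density.volumetric_density(total_mb, total_volume)
            model = identity_density.NucleosomeModel(
                bp_per_nucleosome=config.bp_per_nucleosome,
                core_bp=146.0,
                linker_bp=config.bp_per_nucleosome - 146.0,
                nucleosome_free_fraction=config.nucleosome_free_fraction,
                occupied_volume_nm3=config.occupied_volume_nm3,
            )
            report.update(identity_density.nucleosome_metrics(density, model).as_dict())
            report["total_dna_mb"] = total_mb
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)

        stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(config.manifest(), fh, indent=2)
    except Exception as err:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {err}\n")
        raise PipelineError(f"pipeline stage '{stage}' failed: {err}") from err
    return out
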