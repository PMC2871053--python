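"""Pipeline orchestration and report-table rendering.

Runs preprocess -> map -> annotate -> trailer calling -> quantification over
a reference bundle and a pair (or more) of read libraries, and renders the
standard report tables: per-class composition, top nuclear-enriched miRNAs,
and most abundant tRNA 3' trailers.  A run manifest records the config, the
input/output checksums and per-stage record counts so identical inputs
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotator import AnnotationResult, annotate_cascade, composition_table
from .classes import ClassLabel
from .mapper import AuxReferences, GenomeIndex, MappingResult, map_records
from .preprocess import (
    PreprocessResult,
    iter_reads,
    preprocess_libraries,
)
from .quantify import (
    IsomiRGroup,
    NCRecord,
    assign_rpm,
    concordant_groups,
    group_isomirs,
    hexamer_extract,
    nc_ratio,
    nc_records,
    rpm_normalize,
)
from .reference import (
    ReferenceBundle,
    TrailerRegion,
    build_cca_trnas,
    build_junction_library,
    build_trailer_regions,
    load_bundle,
)
from .trailers import TrailerCall, aggregate_isotrailers, call_trailers


def round_half_up(value: float, digits: int) -> float:
    """Decimal half-up rounding for report tables (Python's round is
    half-even)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def build_aux(bundle: ReferenceBundle) -> AuxReferences:
    """Derive the rescue-stage references from a bundle."""
    rrna_units = [
        (r.ref_id, r.sequence)
        for label in (ClassLabel.RRNA, ClassLabel.ITS, ClassLabel.ETS)
        for r in bundle.refs_of(label)
    ]
    return AuxReferences(
        rrna_units=rrna_units,
        junctions=build_junction_library(bundle),
        cca_trnas=build_cca_trnas(bundle),
        trna_refs=[(r.ref_id, r.sequence) for r in bundle.refs_of(ClassLabel.TRNA)],
    )


@dataclasses.dataclass
class PipelineResult:
    preprocess: PreprocessResult
    mapping: MappingResult
    annotation: AnnotationResult
    mapped_totals: dict[str, int]
    nc: list[NCRecord]
    isomir_groups: list[IsomiRGroup]
    trailer_calls: list[TrailerCall]       # all called trailers
    trailer_calls_kept: list[TrailerCall]  # passing the >10 eligibility
    composition: pd.DataFrame


def run_on_libraries(
    libraries: dict[str, list[tuple[str, int]]],
    bundle: ReferenceBundle,
    adapter3: str,
    adapter5: str = "",
    trailer_regions: list[TrailerRegion] | None = None,
    mirna_catalog=None,
    hairpin_arms=None,
    skip_trim: bool = False,
    index: GenomeIndex | None = None,
) -> PipelineResult:
    """Run the full analysis in memory over (read, count) library streams."""
    pre = preprocess_libraries(libraries, adapter3, adapter5, skip_trim=skip_trim)
    aux = build_aux(bundle)
    if trailer_regions is None:
        trailer_regions = build_trailer_regions(bundle)
    mapping = map_records(pre.records, bundle, aux, index=index)
    annotation = annotate_cascade(
        mapping.mapped(), bundle, trailer_regions, hits=mapping.hits
    )
    mapped_totals = mapping.mapped_totals()
    assign_rpm(annotation.records, mapped_totals)
    nc = nc_records(annotation.records)
    mirna_records = [
        r for r in annotation.records if r.label is ClassLabel.MIRNA
    ]
    groups = group_isomirs(mirna_records, mirna_catalog, hairpin_arms)
    trailer_records = [
        r for r in annotation.records if r.label is ClassLabel.TRNA_TRAILER
    ]
    calls = call_trailers(trailer_records, trailer_regions)
    kept = aggregate_isotrailers(calls)
    composition = composition_table(annotation.class_counts)
    return PipelineResult(
        pre, mapping, annotation, mapped_totals, nc, groups, calls, kept, composition
    )


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def mirna_table(
    result: PipelineResult,
    top_k: int = 10,
    nuclear_lib: str = "nuclear",
    cytoplasmic_lib: str = "cytoplasmic",
    min_count: int = 10,
) -> pd.DataFrame:
    """Top-k nuclear-enriched miRNAs: concordant groups whose representative
    shows raw count > ``min_count`` in at least one library, ranked by N/C
    descending (ties: nuclear RPM descending)."""
    rows = []
    for group in concordant_groups(result.isomir_groups):
        rep = group.representatives[nuclear_lib]
        raw_n = rep.counts.get(nuclear_lib, 0)
        raw_c = rep.counts.get(cytoplasmic_lib, 0)
        if max(raw_n, raw_c) <= min_count:
            continue
        nuc = rep.rpm.get(nuclear_lib, 0.0)
        cyt = rep.rpm.get(cytoplasmic_lib, 0.0)
        if nuc == 0 and cyt == 0:
            continue
        nc, flag = nc_ratio(nuc, cyt)
        if nc is None:
            continue
        rows.append(
            {
                "microRNA": group.mirna_id,
                "sequence": rep.sequence,
                "hexanucleotide": hexamer_extract(rep.sequence),
                "nuclear_rpm": round_half_up(nuc, 1),
                "cytoplasmic_rpm": round_half_up(cyt, 1),
                "nc": round_half_up(nc, 2),
            }
        )
    rows.sort(key=lambda r: (-r["nc"], -r["nuclear_rpm"]))
    return pd.DataFrame(rows[:top_k])


def trailer_table(
    result: PipelineResult,
    top_k: int = 5,
    nuclear_lib: str = "nuclear",
    cytoplasmic_lib: str = "cytoplasmic",
) -> pd.DataFrame:
    """Top-k tRNA 3' trailers by cytoplasmic aggregate RPM, with the most
    abundant cytoplasmic isotrailer as each trailer's sequence."""
    rows = []
    for call in result.trailer_calls_kept:
        totals = call.aggregate_counts()
        nuc = rpm_normalize(totals.get(nuclear_lib, 0), result.mapped_totals[nuclear_lib])
        cyt = rpm_normalize(
            totals.get(cytoplasmic_lib, 0), result.mapped_totals[cytoplasmic_lib]
        )
        if cyt > 0 and nuc > 0:
            nc_val: float | str = round_half_up(nuc / cyt, 5)
        elif cyt == 0:
            nc_val = "nuclear-only"
        else:
            nc_val = "cytoplasmic-only"
        rows.append(
            {
                "tRNA": call.trna_name,
                "sequence": call.representative_seq(),
                "cytoplasmic_rpm": round_half_up(cyt, 1),
                "nuclear_rpm": round_half_up(nuc, 1),
                "nc": nc_val,
                "u_tail": call.u_tail(),
            }
        )
    rows.sort(key=lambda r: -r["cytoplasmic_rpm"])
    return pd.DataFrame(rows[:top_k])


# ---------------------------------------------------------------------------
# File-level driver
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"config {path} must be a mapping")
    for key in ("genome", "refs", "reads"):
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
    for key in ("genome", "refs", "loci"):
        if key in config and config[key] and not Path(config[key]).exists():
            raise FileNotFoundError(f"config {key}: no such file {config[key]}")
    for lib, path_ in config["reads"].items():
        if not Path(path_).exists():
            raise FileNotFoundError(f"config reads.{lib}: no such file {path_}")
    return config


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the full pipeline from a config mapping (or YAML path) and
    write report tables plus a run manifest.  Returns the manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle = load_bundle(config["genome"], config["refs"], config.get("loci"))
    libraries = {
        lib: list(iter_reads(path)) for lib, path in config["reads"].items()
    }
    result = run_on_libraries(
        libraries,
        bundle,
        adapter3=config.get("adapter3", ""),
        adapter5=config.get("adapter5", ""),
        skip_trim=not config.get("adapter3"),
    )

    outputs: dict[str, Path] = {}

    comp = result.composition.copy()
    comp.to_csv(out / "composition.tsv", sep="\t", index=False)
    outputs["composition"] = out / "composition.tsv"

    per_seq = pd.DataFrame(
        {
            "sequence": [r.sequence for r in result.mapping.records],
            "status": [r.status for r in result.mapping.records],
            "via": [r.via or "" for r in result.mapping.records],
            "label": [getattr(r.label, "value", "") for r in result.mapping.records],
            "matched_ref": [r.matched_ref or "" for r in result.mapping.records],
            "trimmed_tail": [r.trimmed_tail for r in result.mapping.records],
            **{
                f"count_{lib}": [r.counts.get(lib, 0) for r in result.mapping.records]
                for lib in libraries
            },
        }
    )
    per_seq.to_csv(out / "annotation.tsv", sep="\t", index=False)
    outputs["annotation"] = out / "annotation.tsv"

    nc_df = pd.DataFrame(
        {
            "sequence": [r.sequence for r in result.nc],
            "nuclear_rpm": [r.nuclear_rpm for r in result.nc],
            "cytoplasmic_rpm": [r.cytoplasmic_rpm for r in result.nc],
            "nc": [r.nc if r.nc is not None else "" for r in result.nc],
            "flag": [r.flag or "" for r in result.nc],
            "eligible": [r.eligible for r in result.nc],
            "label": [getattr(r.label, "value", "") for r in result.nc],
        }
    )
    nc_df.to_csv(out / "nc_table.tsv", sep="\t", index=False)
    outputs["nc_table"] = out / "nc_table.tsv"

    mirna_table(result).to_csv(out / "top_mirnas.tsv", sep="\t", index=False)
    outputs["top_mirnas"] = out / "top_mirnas.tsv"
    trailer_table(result).to_csv(out / "top_trailers.tsv", sep="\t", index=False)
    outputs["top_trailers"] = out / "top_trailers.tsv"

    discard_rows = [
        {"library": lib, "reason": reason, "count": count}
        for lib, log in result.preprocess.discard_log.items()
        for reason, count in sorted(log.items())
    ]
    pd.DataFrame(discard_rows, columns=["library", "reason", "count"]).to_csv(
        out / "discard_log.tsv", sep="\t", index=False
    )
    outputs["discard_log"] = out / "discard_log.tsv"

    manifest = {
        "tool": "srnanc",
        "version": __version__,
        "config": {k: str(v) for k, v in config.items() if k != "reads"},
        "reads": {lib: str(p) for lib, p in config["reads"].items()},
        "seed": config.get("seed"),
        "input_checksums": {
            key: _sha256(Path(config[key]))
            for key in ("genome", "refs", "loci")
            if config.get(key)
        },
        "read_checksums": {
            lib: _sha256(Path(p)) for lib, p in config["reads"].items()
        },
        "stage_counts": {
            "input_reads": result.preprocess.n_input,
            "kept_reads": result.preprocess.n_kept,
            "discarded_preprocess": {
                lib: sum(log.values())
                for lib, log in result.preprocess.discard_log.items()
            },
            "unique_sequences": len(result.mapping.records),
            "mapped_sequences": len(result.mapping.mapped()),
            "mapped_reads": result.mapped_totals,
            "trailer_calls": len(result.trailer_calls),
            "trailer_calls_kept": len(result.trailer_calls_kept),
            "mirna_groups": len(result.isomir_groups),
        },
        "outputs": {name: _sha256(path) for name, path in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
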