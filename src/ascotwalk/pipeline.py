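"""End-to-end pipeline: ingest → discover → quantify → specificity → motifs.

Each stage writes a stable-named artifact into the output directory and
its row counts into a machine-readable run report; a failure stops the
chain, names the failed stage, and leaves earlier artifacts intact.
"""

from __future__ import annotations

import glob as globlib
import hashlib
import json
import logging
import os
from importlib import metadata

import numpy as np

from . import annotation as annotation_mod
from . import discovery as discovery_mod
from . import motifs as motifs_mod
from . import specificity as specificity_mod
from .config import RunConfig
from .junctions import (
    read_junction_matrix,
    read_star_sj,
    write_events_bed,
    write_junction_matrix,
    write_psi_matrix,
)
from .psi import psi_matrix

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    outdir: str | os.PathLike,
    star_glob: str | None = None,
    matrix: str | None = None,
    metadata_path: str | None = None,
    gtf: str | None = None,
    fasta: str | None = None,
) -> dict:
    """Run all applicable stages; returns the run report (also written to
    ``<outdir>/run_report.json``).

    Input is either a glob of STAR SJ files (sample ids from file names)
    or a junction-matrix TSV. Specificity needs sample metadata; the motif
    stage needs a genome FASTA (and a GTF for the baseline) and is skipped
    otherwise.
    """
    os.makedirs(outdir, exist_ok=True)
    outdir = str(outdir)
    try:
        version = metadata.version("ascotwalk")
    except metadata.PackageNotFoundError:
        version = "unknown"
    note = f"ascotwalk config={config.digest()}"
    report: dict = {
        "version": version,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "inputs": {},
        "stages": {},
        "diagnostics": [],
    }

    inputs = {"star_glob": star_glob, "matrix": matrix, "metadata": metadata_path, "gtf": gtf, "fasta": fasta}
    for name, path in inputs.items():
        if path and name != "star_glob" and os.path.exists(path):
            report["inputs"][name] = {"path": path, "sha256": _sha256(path)}

    def fail(stage: str, exc: Exception):
        report["failed_stage"] = stage
        with open(os.path.join(outdir, "run_report.json"), "w") as handle:
            json.dump(report, handle, indent=2)
        raise PipelineError(stage, exc) from exc

    # --- ingest ------------------------------------------------------------
    try:
        if (star_glob is None) == (matrix is None):
            raise ValueError("provide exactly one of star_glob / matrix")
        if star_glob is not None:
            paths = sorted(globlib.glob(star_glob))
            if not paths:
                raise FileNotFoundError(f"no files match {star_glob!r}")
            sample_ids = [
                os.path.basename(p).removesuffix(".SJ.out.tab").removesuffix(".tab")
                for p in paths
            ]
            report["inputs"]["star_files"] = [
                {"path": p, "sha256": _sha256(p)} for p in paths
            ]
            table = read_star_sj(paths, sample_ids, min_intron_length=config.min_intron_length)
            if metadata_path:
                from .junctions import read_sample_metadata

                meta = read_sample_metadata(metadata_path)
                table.groups = {s: meta.get(s, "ungrouped") for s in table.samples}
        else:
            table = read_junction_matrix(
                matrix, metadata_path, min_intron_length=config.min_intron_length
            )
        write_junction_matrix(table, os.path.join(outdir, "junctions.tsv"))
        report["stages"]["ingest"] = {
            "n_junctions": len(table),
            "n_samples": table.n_samples,
        }
    except Exception as exc:  # noqa: BLE001 - report then re-raise
        fail("ingest", exc)

    # --- discover ----------------------------------------------------------
    try:
        dconf = discovery_mod.DiscoveryConfig(
            min_reads=config.min_reads,
            min_samples=config.min_samples,
            mxe_noise_frac=config.mxe_noise_frac,
            max_linked=config.max_linked,
            max_exon_span=config.max_exon_span,
        )
        result = discovery_mod.discover(table, dconf)
        events = result.events
        annotation_exons = None
        if gtf:
            annotation_exons = annotation_mod.exon_key_set(
                annotation_mod.load_gtf_exons(gtf)
            )
        events = discovery_mod.annotate_events(events, annotation_exons)
        discovery_mod.write_events_tsv(
            events, os.path.join(outdir, "events.tsv"), header_comment=note
        )
        report["diagnostics"] = [
            {**d, "flanks": list(d["flanks"]), "exons": [list(x) for x in d["exons"]]}
            for d in result.diagnostics
        ]
        counts_by_type: dict[str, int] = {}
        for ev in events:
            counts_by_type[ev.event_type] = counts_by_type.get(ev.event_type, 0) + 1
        report["stages"]["discover"] = {
            "n_events": len(events),
            "by_type": counts_by_type,
            "n_unannotated": sum(ev.annotated == "unannotated" for ev in events),
            "n_dropped_non_binary": len(result.diagnostics),
        }
    except Exception as exc:  # noqa: BLE001
        fail("discover", exc)

    # --- quantify ----------------------------------------------------------
    try:
        psi = psi_matrix(
            events, table, min_informative=config.min_informative, convention=config.psi_convention
        )
        write_psi_matrix(psi, os.path.join(outdir, "psi.tsv"), header_comment=note)
        write_events_bed(events, psi, os.path.join(outdir, "events.bed"))
        report["stages"]["quantify"] = {
            "n_cells": int(psi.psi.size),
            "n_missing": int(np.isnan(psi.psi).sum()),
        }
    except Exception as exc:  # noqa: BLE001
        fail("quantify", exc)

    # --- specificity -------------------------------------------------------
    if table.groups:
        try:
            summaries = specificity_mod.group_means(psi, table.groups, config.min_group_n)
            calls = specificity_mod.call_specific(
                summaries, config.threshold, config.min_groups_informative
            )
            frame = specificity_mod.summaries_frame(summaries)
            frame.round(1).to_csv(os.path.join(outdir, "group_means.tsv"), sep="\t", na_rep="NA")
            specificity_mod.calls_frame(calls).to_csv(
                os.path.join(outdir, "specificity_calls.tsv"), sep="\t", index=False
            )
            report["stages"]["specificity"] = {
                "n_groups": frame.shape[1],
                "n_calls": len(calls),
            }
        except Exception as exc:  # noqa: BLE001
            fail("specificity", exc)

    # --- motifs ------------------------------------------------------------
    if fasta:
        try:
            from pyfaidx import Fasta

            genome = Fasta(fasta)
            profiles = motifs_mod.positional_profile(
                events,
                genome,
                motif=config.motif,
                bin_width=config.bin_width,
                intronic_flank=config.intronic_flank,
                exonic_flank=config.exonic_flank,
            )
            if gtf:
                baselines = motifs_mod.baseline_profile(
                    gtf,
                    genome,
                    motif=config.motif,
                    max_exon_len=config.baseline_max_exon_len,
                    bin_width=config.bin_width,
                    intronic_flank=config.intronic_flank,
                    exonic_flank=config.exonic_flank,
                )
                profiles = motifs_mod.attach_baseline(profiles, baselines)
            frame = motifs_mod.profiles_frame(profiles)
            with open(os.path.join(outdir, "motif_profile.tsv"), "w") as handle:
                handle.write(f"# {note}\n")
                frame.to_csv(handle, sep="\t", index=False, na_rep="NA")
            report["stages"]["motifs"] = {
                "total_count": int(sum(p.counts.sum() for p in profiles.values())),
                "n_event_exons": profiles["5prime_ss"].n_exons,
            }
        except Exception as exc:  # noqa: BLE001
            fail("motifs", exc)

    with open(os.path.join(outdir, "run_report.json"), "w") as handle:
        json.dump(report, handle, indent=2)
    return report
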