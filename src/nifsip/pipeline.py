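"""End-to-end pipeline orchestration: curate -> place/ingest -> classify
[-> sip-detect], with a run manifest for reproducibility.

Given one YAML config, the stages run in the published order and every output
is a deterministic TSV/jplace/JSON file; rerunning with the same config and
seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .placement import (
    ReferenceTree,
    place_query,
    read_placements,
    write_placements,
)
from .refdb import curate_references, filter_amplicon_lengths
from .sip import SipConfig
from .taxonomy import ClassifierConfig, classify, identity_report
from . import io as nio

__all__ = ["PipelineConfig", "run_pipeline", "ConfigError"]

log = logging.getLogger("nifsip.pipeline")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run.

    Either ``placements`` (a jplace file from an external placer) or the
    triple ``queries_fasta`` + ``ref_alignment`` + ``tree`` must be given.
    Relative paths resolve against the config file's directory.
    """

    reference_fasta: str
    lineages: str
    tree: str | None = None
    placements: str | None = None
    queries_fasta: str | None = None
    ref_alignment: str | None = None
    sip_counts: str | None = None
    sip_metadata: str | None = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    sip: SipConfig = field(default_factory=SipConfig)
    amplicon_window: tuple[int, int] = (330, 370)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            if p is None:
                return None
            return p if os.path.isabs(p) else os.path.join(base, p)

        cls_kwargs: dict[str, Any] = {}
        for key in (
            "reference_fasta",
            "lineages",
            "tree",
            "placements",
            "queries_fasta",
            "ref_alignment",
            "sip_counts",
            "sip_metadata",
        ):
            if key in raw:
                cls_kwargs[key] = resolve(raw[key])
        if "classifier" in raw:
            cls_kwargs["classifier"] = ClassifierConfig(**raw["classifier"])
        if "sip" in raw:
            sip_raw = dict(raw["sip"])
            if "windows" in sip_raw:
                sip_raw["windows"] = tuple(
                    tuple(w) for w in sip_raw["windows"]
                )
            cls_kwargs["sip"] = SipConfig(**sip_raw)
        if "amplicon_window" in raw:
            cls_kwargs["amplicon_window"] = tuple(raw["amplicon_window"])
        if "seed" in raw:
            cls_kwargs["seed"] = int(raw["seed"])
        try:
            return cls(**cls_kwargs)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def validate(self) -> None:
        required = {"reference_fasta": self.reference_fasta, "lineages": self.lineages}
        if self.placements is None:
            if not (self.queries_fasta and self.ref_alignment and self.tree):
                raise ConfigError(
                    "config needs either 'placements' (jplace) or "
                    "'queries_fasta' + 'ref_alignment' + 'tree'"
                )
            required.update(
                queries_fasta=self.queries_fasta,
                ref_alignment=self.ref_alignment,
                tree=self.tree,
            )
        else:
            required["placements"] = self.placements
        if self.sip_counts or self.sip_metadata:
            if not (self.sip_counts and self.sip_metadata):
                raise ConfigError(
                    "SIP detection needs both 'sip_counts' and 'sip_metadata'"
                )
            required.update(sip_counts=self.sip_counts, sip_metadata=self.sip_metadata)
        for name, path in required.items():
            if path is None:
                raise ConfigError(f"missing required path: {name}")
            if not os.path.exists(path):
                raise ConfigError(f"{name}: no such file {path!r}")

    def to_canonical_dict(self) -> dict:
        """Config content (basenames only, so the hash is location-free)."""
        d: dict[str, Any] = {
            "seed": self.seed,
            "amplicon_window": list(self.amplicon_window),
            "classifier": {
                "k": self.classifier.k,
                "rank_order": list(self.classifier.rank_order),
                "annotation_rank": self.classifier.annotation_rank,
            },
            "sip": {
                "windows": [list(w) for w in self.sip.windows],
                "null_lfc": self.sip.null_lfc,
                "fdr": self.sip.fdr,
                "prefilter_ratio": self.sip.prefilter_ratio,
                "prefilter_min_fractions": self.sip.prefilter_min_fractions,
                "prefilter_density_cutoff": self.sip.prefilter_density_cutoff,
            },
        }
        for key in (
            "reference_fasta",
            "lineages",
            "tree",
            "placements",
            "queries_fasta",
            "ref_alignment",
            "sip_counts",
            "sip_metadata",
        ):
            val = getattr(self, key)
            d[key] = None if val is None else os.path.basename(val)
        return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str) -> dict[str, str]:
    """Run all configured stages; returns a name -> path map of outputs."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    outputs: dict[str, str] = {}

    def opath(name: str) -> str:
        outputs[name] = os.path.join(outdir, name)
        return outputs[name]

    # --- stage 1: curation ------------------------------------------------
    log.info("curate: reading %s", config.reference_fasta)
    raw = nio.read_raw_records(config.reference_fasta, config.lineages)
    result = curate_references(raw)
    log.info(
        "curate: kept %d / %d records (rejections: %s)",
        len(result.kept),
        result.n_input,
        result.rejections,
    )
    nio.write_fasta(
        opath("curated.fasta"), [(r.id, r.sequence) for r in result.kept]
    )
    report = pd.DataFrame(
        {"id": list(result.outcomes), "outcome": list(result.outcomes.values())}
    )
    nio.write_tsv(opath("curation_report.tsv"), report)
    lineages = {r.id: r.lineage for r in result.kept}

    # --- stage 2: placement (ingest or built-in) --------------------------
    query_seqs = None
    ref_seqs = None
    if config.placements is not None:
        log.info("place: ingesting %s", config.placements)
        rt, placements = read_placements(config.placements, lineages)
    else:
        log.info("place: built-in placement of %s", config.queries_fasta)
        rt = ReferenceTree.from_newick(config.tree, lineages)
        ref_seqs = dict(nio.read_fasta(config.ref_alignment))
        queries = nio.read_fasta(config.queries_fasta)
        lo, hi = config.amplicon_window
        kept_queries = filter_amplicon_lengths(queries, lo, hi)
        log.info(
            "place: %d / %d queries inside the %d-%d bp window",
            len(kept_queries), len(queries), lo, hi,
        )
        query_seqs = dict(kept_queries)
        placements = [
            place_query(qid, seq, ref_seqs, rt) for qid, seq in kept_queries
        ]
        write_placements(opath("placements.jplace"), rt, placements)
    if not rt.leaf_lineages:
        rt.leaf_lineages = lineages

    # --- stage 3: classification ------------------------------------------
    log.info("classify: k=%.3g", config.classifier.k)
    assignments = classify(rt, placements, config.classifier)
    ident = {}
    if query_seqs is not None and ref_seqs is not None:
        df_ident, _ = identity_report(assignments, query_seqs, ref_seqs)
        ident = dict(zip(df_ident["query_id"], df_ident["nearest_identity"]))
    rows = []
    for a in sorted(assignments, key=lambda a: a.query_id):
        nn_label, nn_dist = a.nearest_neighbor or ("", float("nan"))
        rows.append(
            {
                "query_id": a.query_id,
                "status": a.status,
                "lineage": a.lineage_string(),
                "depth": a.depth_achieved or "",
                "nearest_neighbor": nn_label,
                "nearest_distance": nn_dist,
                "nearest_identity": ident.get(a.query_id, ""),
            }
        )
    nio.write_tsv(opath("assignments.tsv"), pd.DataFrame(rows))
    log.info(
        "classify: %d / %d classified at %s",
        sum(a.status == "classified" for a in assignments),
        len(assignments),
        config.classifier.annotation_rank,
    )

    # --- stage 4: SIP detection (optional) --------------------------------
    if config.sip_counts:
        from .sip import detect

        log.info("sip-detect: %s", config.sip_counts)
        tables = nio.load_fraction_tables(config.sip_counts, config.sip_metadata)
        for needed in ("control", "treatment"):
            if needed not in tables:
                raise ConfigError(
                    f"{config.sip_metadata}: no condition named {needed!r}"
                )
        sres = detect(tables["control"], tables["treatment"], config.sip)
        nio.write_tsv(opath("incorporators.tsv"), sres.incorporators)
        nio.write_tsv(opath("sip_windows.tsv"), sres.long_table())
        log.info("sip-detect: %d incorporators", len(sres.incorporators))

    # --- manifest ---------------------------------------------------------
    manifest = {
        "package": f"nifsip {__version__}",
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_canonical_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    mpath = os.path.join(outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["manifest.json"] = mpath
    return outputs
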