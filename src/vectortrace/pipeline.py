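"""End-to-end drivers tying the stages into the two emulated analyses.

``run_integration_assay`` goes from an alignment file on the combined
reference to classified integration sites; ``run_editing_quant`` goes from
allele models + primers (+ optional amplicon reads) to band-based HDR and
window-based indel estimates.  Both return plain dicts that
``make_report`` merges into one schema-checked, deterministically ordered
report.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from . import editing_quant as eq
from . import junction_caller as jc
from .vector_model import TargetLocus, VectorMap


@dataclass
class RunConfig:
    """Thresholds and paths for a pipeline run; unknown keys are rejected."""

    seed: int = 0
    genome: str | None = None
    vector_map: str | None = None
    locus: str | None = None
    alignments: str | None = None
    reads: str | None = None
    out_dir: str = "."
    min_mapq: int = jc.DEFAULT_MIN_MAPQ
    min_segment_len: int = jc.DEFAULT_MIN_SEGMENT_LEN
    max_junction_gap: int = jc.DEFAULT_MAX_JUNCTION_GAP
    merge_distance: int = jc.DEFAULT_MERGE_DISTANCE
    min_support: int = 1
    targeted_window: int = jc.DEFAULT_TARGETED_WINDOW
    window_bp: int = eq.DEFAULT_WINDOW_BP
    min_indel_len: int = eq.DEFAULT_MIN_INDEL_LEN
    max_mismatches: int = 4

    _RANGES = {
        "min_mapq": (0, 60),
        "min_segment_len": (1, 100_000),
        "max_junction_gap": (0, 10_000),
        "merge_distance": (0, 100_000),
        "min_support": (1, 1_000_000),
        "targeted_window": (0, 1_000_000),
        "window_bp": (1, 1_000),
        "min_indel_len": (1, 1_000),
        "max_mismatches": (0, 6),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"config {name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        obj = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_integration_assay(
    alignments: str | Path,
    vector_map: VectorMap,
    locus: TargetLocus,
    config: RunConfig | None = None,
    predicted_offtargets: list[tuple[int, int]] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Alignment file → junction events → clustered, classified sites.

    Writes ``sites.bed``, ``junctions.tsv`` and ``summary.json`` under
    *out_dir* when given; always returns the summary dict.
    """
    cfg = config or RunConfig()
    events = jc.call_junctions_from_alignments(
        alignments,
        vector_contig=vector_map.name,
        vector_map=vector_map,
        min_mapq=cfg.min_mapq,
        min_segment_len=cfg.min_segment_len,
        max_junction_gap=cfg.max_junction_gap,
    )
    sites = jc.cluster_sites(events, merge_distance=cfg.merge_distance, min_support=cfg.min_support)
    classification = jc.classify_sites(
        sites, locus, targeted_window=cfg.targeted_window, predicted_offtargets=predicted_offtargets
    )
    summary = {"analysis": "integration_assay", **jc.summarize_sites(sites), "n_junction_events": len(events)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        jc.write_sites_bed(sites, out / "sites.bed")
        jc.write_junctions_tsv(events, out / "junctions.tsv")
        classification.to_csv(out / "site_classification.tsv", sep="\t", index=False)
        jc.write_summary_json(summary, out / "summary.json")
        cfg.to_json(out / "resolved_config.json")
    summary["sites"] = classification.to_dict(orient="records")
    return summary


def run_editing_quant(
    alleles,
    primers: eq.PrimerSet,
    reads=None,
    reference_amplicon: str | None = None,
    cut_site_in_amplicon: int | None = None,
    vector_sequence: str | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Three-primer PCR prediction → band table → HDR fraction, plus the
    window indel fraction when amplicon *reads* are given.

    If *vector_sequence* is supplied the outer-primer pair is first checked
    for episome specificity: any outer-pair product on the episome is a
    hard error, because such primers would amplify non-integrated vector.
    """
    cfg = config or RunConfig()
    if vector_sequence is not None:
        # any outer-pair product on the episome disqualifies the primer set,
        # regardless of the gel's usable size range
        episome_products = [
            p
            for p in eq.insilico_pcr(
                vector_sequence, primers, max_len=max(len(vector_sequence), 51)
            )
            if set(p.primer_pair) == {"p_out5", "p_out3"}
        ]
        if episome_products:
            raise ValueError(
                "outer primer pair amplifies the vector episome; the assay "
                "cannot distinguish integrated from episomal template"
            )
    predicted = eq.predict_bands(alleles, primers)
    result: dict = {
        "analysis": "editing_quant",
        "predicted_products": predicted.to_dict(orient="records"),
    }
    if reads is not None:
        read_list = eq._load_reads(reads)
        bands = eq.band_table_from_read_lengths([len(s) for _, s in read_list], predicted)
        result["bands"] = bands.to_dict(orient="records")
        result["hdr_fraction"] = eq.quantify_hdr_from_bands(bands)
        result["n_reads"] = len(read_list)
        if reference_amplicon is not None and cut_site_in_amplicon is not None:
            upper_len = int(
                bands.loc[bands["allele_class"] == "WT/NHEJ", "predicted_length"].iloc[0]
            )
            upper_reads = [
                (rid, s)
                for rid, s in read_list
                if abs(len(s) - upper_len) <= 0.15 * upper_len
            ]
            res = eq.call_indels_window(
                upper_reads,
                reference_amplicon,
                cut_site_in_amplicon,
                window_bp=cfg.window_bp,
                min_indel_len=cfg.min_indel_len,
            )
            result["indel_fraction"] = res.indel_fraction
            result["n_reads_indel_analyzed"] = res.n_reads_analyzed
        else:
            result["indel_fraction"] = None
    else:
        result["bands"] = None
        result["hdr_fraction"] = None
        result["indel_fraction"] = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        predicted.to_csv(out / "predicted_products.tsv", sep="\t", index=False)
        if result.get("bands"):
            import pandas as pd

            pd.DataFrame(result["bands"]).to_csv(out / "bands.tsv", sep="\t", index=False)
        Path(out / "editing_summary.json").write_text(
            json.dumps({k: v for k, v in result.items() if k != "predicted_products"},
                       indent=1, sort_keys=True, default=float) + "\n"
        )
    return result


_REPORT_KEYS = {"analysis"}


def make_report(summaries: list[dict]) -> dict:
    """Merge per-analysis summaries into one deterministic report."""
    if not summaries:
        raise ValueError("make_report needs at least one summary")
    report: dict = {"sections": {}}
    for summary in summaries:
        missing = _REPORT_KEYS - set(summary)
        if missing:
            raise ValueError(f"summary missing required keys: {sorted(missing)}")
        name = summary["analysis"]
        report["sections"][name] = {k: summary[k] for k in sorted(summary) if k != "analysis"}
    report["sections"] = dict(sorted(report["sections"].items()))
    return report


def write_report(report: dict, json_path: str | Path, text_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(report, indent=1, sort_keys=True, default=float) + "\n")
    if text_path is not None:
        lines = []
        for name, section in report["sections"].items():
            lines.append(f"== {name} ==")
            for k, v in section.items():
                if isinstance(v, (list, dict)):
                    continue
                lines.append(f"  {k}: {v}")
            lines.append("")
        Path(text_path).write_text("\n".join(lines))
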