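"""File formats: FASTA clones with key=value metadata, TSV tables, YAML specs.

Every TSV/JSON output starts with a comment header naming the package,
a config hash and the seed, so results are traceable to the run that
produced them; pandas readers skip these lines via ``comment='#'``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import CloneClassification, DSBCall
from .locus import LocusReference, load_locus_spec, serialize_locus
from .simulate import CloneRecord, GynoTruth, TruthRecord
from .stats import FrequencyReport, GynoGenotype


@dataclass
class RunConfig:
    """Resolved configuration of one CLI run (hashed into output headers)."""

    subcommand: str
    locus_spec: str | None = None
    inputs: tuple = ()
    metadata: str | None = None
    outdir: str = "."
    seed: int = 0
    log_level: str = "INFO"
    params: dict | None = None

    def hash(self) -> str:
        blob = json.dumps(
            {
                "subcommand": self.subcommand,
                "locus_spec": self.locus_spec,
                "inputs": list(self.inputs),
                "metadata": self.metadata,
                "seed": self.seed,
                "params": self.params or {},
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(config: RunConfig | None) -> str:
    if config is None:
        return "# gtrec\n"
    return f"# gtrec config={config.hash()} seed={config.seed}\n"


# ---------------------------------------------------------------------------
# Locus specs
# ---------------------------------------------------------------------------

def read_locus_spec(path) -> LocusReference:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return load_locus_spec(doc)


def write_locus_spec(locus: LocusReference, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(serialize_locus(locus), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_clone_fasta(clones: list[CloneRecord], path) -> None:
    """Clones as FASTA; sample/individual metadata as key=value pairs in the
    description, keeping the records standard-FASTA compatible."""
    records = []
    for c in clones:
        desc = []
        if c.sample:
            desc.append(f"sample={c.sample}")
        if c.individual:
            desc.append(f"individual={c.individual}")
        records.append(
            SeqRecord(Seq(c.seq), id=c.clone_id, description=" ".join(desc))
        )
    SeqIO.write(records, str(path), "fasta")


def read_clone_fasta(path, metadata: pd.DataFrame | None = None) -> list[CloneRecord]:
    """Read clones; a sidecar metadata table (clone_id, sample, individual)
    overrides header key=value pairs."""
    meta_map = {}
    if metadata is not None:
        for row in metadata.itertuples():
            meta_map[row.clone_id] = row
    clones = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = {}
        for tok in rec.description.split()[1:]:
            if "=" in tok:
                k, v = tok.split("=", 1)
                kv[k] = v
        sample = kv.get("sample")
        individual = kv.get("individual")
        if rec.id in meta_map:
            row = meta_map[rec.id]
            sample = getattr(row, "sample", sample) or sample
            individual = getattr(row, "individual", individual) or individual
        clones.append(
            CloneRecord(
                clone_id=rec.id,
                seq=str(rec.seq).upper(),
                sample=sample,
                individual=individual,
            )
        )
    return clones


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _write_df(df: pd.DataFrame, path, config: RunConfig | None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def write_truth_tsv(truths: list[TruthRecord], path, config: RunConfig | None = None) -> None:
    df = pd.DataFrame(
        {
            "clone_id": [t.clone_id for t in truths],
            "sample": [t.sample or "" for t in truths],
            "true_class": [t.true_class for t in truths],
            "breakpoints": [",".join(map(str, t.true_breakpoints)) for t in truths],
            "motif1_units": [t.true_motif1_units for t in truths],
            "dsb_parent": [t.dsb_parent for t in truths],
            "slipped": [t.slipped for t in truths],
            "chimeric": [t.chimeric for t in truths],
        }
    )
    _write_df(df, path, config)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)


def write_calls_tsv(calls_by_clone: dict, path, config: RunConfig | None = None) -> None:
    rows = []
    for clone_id, calls in calls_by_clone.items():
        for c in calls:
            rows.append(
                {
                    "clone_id": clone_id,
                    "marker_id": c.marker_id,
                    "call": c.call,
                    "observed_allele": c.observed_allele if c.observed_allele is not None else "",
                }
            )
    _write_df(pd.DataFrame(rows), path, config)


def write_repeats_tsv(repeats_by_clone: dict, path, config: RunConfig | None = None) -> None:
    rows = []
    for clone_id, repeats in repeats_by_clone.items():
        for r in repeats:
            rows.append(
                {
                    "clone_id": clone_id,
                    "motif_id": r.motif_id,
                    "observed_units": "" if r.observed_units is None else r.observed_units,
                    "matches": r.matches,
                    "delta_vs_nearest_parent": ""
                    if r.delta_vs_nearest_parent is None
                    else r.delta_vs_nearest_parent,
                }
            )
    _write_df(pd.DataFrame(rows), path, config)


def write_classification_tsv(
    classifications: list[CloneClassification],
    dsb_calls: dict[str, DSBCall],
    path,
    config: RunConfig | None = None,
) -> None:
    rows = []
    for c in classifications:
        meas = c.motif1_measurement
        dsb = dsb_calls.get(c.clone_id)
        rows.append(
            {
                "clone_id": c.clone_id,
                "sample": c.sample or "",
                "individual": c.individual or "",
                "clone_class": c.clone_class,
                "n_switches": c.n_switches,
                "breakpoint_intervals": ";".join(
                    f"{lo}-{hi}" for lo, hi in c.breakpoint_intervals
                ),
                "motif1_units": ""
                if meas is None or meas.observed_units is None
                else meas.observed_units,
                "dsb_origin": dsb.origin if dsb else "",
                "excluded": c.excluded,
            }
        )
    _write_df(pd.DataFrame(rows), path, config)


def read_classification_tsv(path) -> list[CloneClassification]:
    from .calling import RepeatMeasurement

    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    out = []
    for row in df.itertuples():
        intervals = []
        if row.breakpoint_intervals:
            for part in str(row.breakpoint_intervals).split(";"):
                lo, hi = part.split("-")
                intervals.append((int(lo), int(hi)))
        units = None if row.motif1_units == "" else int(row.motif1_units)
        meas = (
            None
            if units is None
            else RepeatMeasurement("motif1", units, "other", None)
        )
        out.append(
            CloneClassification(
                clone_id=str(row.clone_id),
                clone_class=row.clone_class,
                breakpoint_intervals=intervals,
                motif1_measurement=meas,
                n_switches=int(row.n_switches),
                sample=str(row.sample) or None,
                individual=str(row.individual) or None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def frequency_report_frame(reports: dict[str, FrequencyReport]) -> pd.DataFrame:
    rows = []
    for sample, r in sorted(reports.items()):
        row = {"sample_id": sample, **{f"n_{k}": v for k, v in r.counts.items()}}
        row.update(
            n_retained=r.n_retained,
            n_excluded=r.n_excluded,
            hr_percent=r.hr_percent,
            hr_ci_low=None if r.hr_ci is None else round(100 * r.hr_ci[0], 2),
            hr_ci_high=None if r.hr_ci is None else round(100 * r.hr_ci[1], 2),
            flagged=r.flagged,
        )
        for cls in ("PD", "MD", "CO_I", "CO_II", "CO_I_II"):
            row[f"pct_{cls}"] = r.class_percent(cls)
        rows.append(row)
    return pd.DataFrame(rows)


def write_frequency_report(
    reports: dict[str, FrequencyReport], path, config: RunConfig | None = None
) -> None:
    _write_df(frequency_report_frame(reports), path, config)


def write_gynogenote_report(
    genotypes: list[GynoGenotype], path, config: RunConfig | None = None
) -> None:
    df = pd.DataFrame(
        {
            "individual_id": [g.individual_id for g in genotypes],
            "genotype": [g.genotype or "withheld" for g in genotypes],
            "patterns": ["+".join(g.patterns) for g in genotypes],
            "n_clones": [g.n_clones for g in genotypes],
            "withheld": [g.withheld for g in genotypes],
        }
    )
    _write_df(df, path, config)


def write_json_report(obj: dict, path, config: RunConfig | None = None) -> None:
    payload = dict(obj)
    if config is not None:
        payload["_meta"] = {"tool": "gtrec", "config": config.hash(), "seed": config.seed}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
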