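"""Tabular input/output and the site/panel filters.

Formats (all tab-separated, header required, UTF-8, '.' for missing,
1-based inclusive positions):

* frequency table — columns ``chrom pos anc der x`` with ``x`` the modern
  derived-allele frequency; alternatively a plain VCF whose INFO field
  carries the frequency (``AF`` by default, taken for the first ALT).
* read-count table — columns ``chrom pos ind n_anc n_der``: per site and
  individual, counts of reads showing the ancestral and derived allele.
  Counting reads (and the choice to treat third alleles as errors or drop
  the site) happens upstream, e.g. from ``samtools mpileup`` output.
* panel table — columns ``ind pop`` plus optional extras; groups
  individuals into ancient populations analyzed jointly.

The loader joins on (chrom, pos), keeps one dataset per population, and
accounts for every dropped site: non-segregating modern frequency, no
frequency record, or no reads in the panel.  The modern frequency is
taken as known (finite-panel noise in x is not modeled).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import ContinuityTest, Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "FilterReport",
    "read_frequency_table",
    "read_frequencies_vcf",
    "read_read_counts",
    "read_panel",
    "read_inputs",
    "write_results",
    "results_table",
    "RESULT_COLUMNS",
]


class ParseError(ValueError):
    """An input file violates the documented schema."""


FREQ_COLUMNS = ["chrom", "pos", "anc", "der", "x"]
READ_COLUMNS = ["chrom", "pos", "ind", "n_anc", "n_der"]
PANEL_COLUMNS = ["ind", "pop"]
RESULT_COLUMNS = [
    "pop", "cov", "t1", "t2", "lnL", "t1_cont", "lnL_cont",
    "lrt", "p_chi2_1df", "p_mixture", "status",
]


@dataclass
class FilterReport:
    """Per-population accounting of site filtering.

    Invariant (asserted): sites_in == sites_used + sum of drop counts.
    """

    sites_in: int = 0
    sites_used: int = 0
    dropped_nonsegregating: int = 0
    dropped_no_frequency: int = 0
    dropped_no_reads: int = 0

    def check(self) -> None:
        dropped = (
            self.dropped_nonsegregating
            + self.dropped_no_frequency
            + self.dropped_no_reads
        )
        assert self.sites_in == self.sites_used + dropped, dataclasses.asdict(self)


def _read_tsv(path, columns, dtypes=None):
    try:
        df = pd.read_csv(path, sep="\t", na_values=["."], dtype=dtypes)
    except (OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_frequency_table(path) -> pd.DataFrame:
    """Load a frequency TSV; duplicate (chrom, pos) keys are an error."""
    df = _read_tsv(path, FREQ_COLUMNS, dtypes={"chrom": str})
    dup = df.duplicated(["chrom", "pos"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate site {row['chrom']}:{row['pos']} (line {dup.idxmax() + 2})"
        )
    if df["x"].isna().any() or (df["x"] < 0).any() or (df["x"] > 1).any():
        bad = int(df.index[df["x"].isna() | (df["x"] < 0) | (df["x"] > 1)][0])
        raise ParseError(f"{path}: frequency outside [0, 1] at line {bad + 2}")
    return df[FREQ_COLUMNS]


def read_frequencies_vcf(path, info_field: str = "AF") -> pd.DataFrame:
    """Extract modern derived frequencies from a VCF.

    Uses the first ALT allele as the derived allele and ``info_field``
    (first value if per-allele) as its frequency; REF is taken as
    ancestral.  Multi-allelic records beyond the first ALT are ignored.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            if info_field not in rec.info:
                raise ParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks INFO/{info_field}"
                )
            val = rec.info[info_field]
            x = float(val[0]) if isinstance(val, tuple) else float(val)
            # INFO floats come back as float32; round to the precision a
            # VCF text field realistically carries
            rows.append((str(rec.chrom), int(rec.pos), rec.ref, rec.alts[0], round(x, 6)))
    df = pd.DataFrame(rows, columns=FREQ_COLUMNS)
    if df.duplicated(["chrom", "pos"]).any():
        raise ParseError(f"{path}: duplicate sites in VCF")
    return df


def read_read_counts(path) -> pd.DataFrame:
    df = _read_tsv(path, READ_COLUMNS, dtypes={"chrom": str, "ind": str})
    for col in ("n_anc", "n_der"):
        vals = df[col]
        if vals.isna().any() or (vals < 0).any() or (vals != vals.astype(int)).any():
            bad = int(vals.index[vals.isna() | (vals < 0)][0]) if vals.isna().any() or (vals < 0).any() else int(vals.index[vals != vals.astype(int)][0])
            raise ParseError(f"{path}: {col} must be a non-negative integer (line {bad + 2})")
    dup = df.duplicated(["chrom", "pos", "ind"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate entry {row['chrom']}:{row['pos']} {row['ind']}"
        )
    return df


def read_panel(path) -> pd.DataFrame:
    df = _read_tsv(path, PANEL_COLUMNS, dtypes={"ind": str, "pop": str})
    if df["ind"].duplicated().any():
        raise ParseError(f"{path}: duplicate individual in panel")
    if df["pop"].isna().any():
        raise ParseError(f"{path}: missing population label")
    return df


def read_inputs(freq_path, reads_path, panel_path, vcf: bool = False):
    """Join frequency, read-count and panel files into per-population datasets.

    Returns ``(datasets, reports)``: dicts keyed by population label with
    :class:`~continuitest.inference.Dataset` values and
    :class:`FilterReport` accounting.
    """
    freqs = read_frequencies_vcf(freq_path) if vcf else read_frequency_table(freq_path)
    reads = read_read_counts(reads_path)
    panel = read_panel(panel_path)

    unknown = set(reads["ind"]) - set(panel["ind"])
    if unknown:
        raise ParseError(
            f"{reads_path}: individuals absent from the panel: {sorted(unknown)}"
        )

    freq_idx = freqs.set_index(["chrom", "pos"])["x"]
    datasets: dict[str, Dataset] = {}
    reports: dict[str, FilterReport] = {}
    for pop, members in panel.groupby("pop", sort=True):
        inds = list(members["ind"])
        sub = reads[reads["ind"].isin(inds)]
        if sub.empty:
            raise ParseError(f"no read counts for population {pop!r}")
        wide_a = sub.pivot_table(
            index=["chrom", "pos"], columns="ind", values="n_anc", fill_value=0
        ).reindex(columns=inds, fill_value=0)
        wide_d = sub.pivot_table(
            index=["chrom", "pos"], columns="ind", values="n_der", fill_value=0
        ).reindex(columns=inds, fill_value=0)

        report = FilterReport(sites_in=len(wide_a))
        x = freq_idx.reindex(wide_a.index)
        has_freq = x.notna().to_numpy()
        report.dropped_no_frequency = int((~has_freq).sum())
        xv = x.to_numpy(dtype=float)
        seg = has_freq & (xv > 0.0) & (xv < 1.0)
        report.dropped_nonsegregating = int((has_freq & ~seg).sum())
        a = wide_a.to_numpy(dtype=np.int64)
        d = wide_d.to_numpy(dtype=np.int64)
        has_reads = (a + d).sum(axis=1) > 0
        keep = seg & has_reads
        report.dropped_no_reads = int((seg & ~has_reads).sum())
        report.sites_used = int(keep.sum())
        report.check()
        if report.sites_used == 0:
            raise ParseError(
                f"population {pop!r}: no usable sites after joining and filtering"
            )
        logger.info(
            "population %s: %d/%d sites used", pop, report.sites_used, report.sites_in
        )
        datasets[pop] = Dataset(xv[keep], a[keep], d[keep], individuals=inds)
        reports[pop] = report
    return datasets, reports


RESULTS_SCHEMA = {
    "type": "object",
    "required": ["populations", "config"],
    "properties": {
        "populations": {
            "type": "object",
            "values": {
                "type": "object",
                "required": ["status"],
            },
        },
        "config": {"type": "object"},
    },
}


def validate_results_json(obj) -> None:
    """Minimal structural validation against :data:`RESULTS_SCHEMA`."""
    if not isinstance(obj, dict):
        raise ParseError("results JSON must be an object")
    for key in RESULTS_SCHEMA["required"]:
        if key not in obj:
            raise ParseError(f"results JSON missing key {key!r}")
    if not isinstance(obj["populations"], dict) or not isinstance(obj["config"], dict):
        raise ParseError("results JSON: 'populations' and 'config' must be objects")
    for pop, entry in obj["populations"].items():
        if not isinstance(entry, dict) or "status" not in entry:
            raise ParseError(f"results JSON: population {pop!r} lacks a status")


def mean_coverage(data: Dataset) -> float:
    """Mean reads per individual per site, the 'cov' column of the output."""
    return float((data.a + data.d).sum() / (data.n_sites * data.n_individuals))


def results_table(results: dict, datasets: dict | None = None) -> pd.DataFrame:
    """Arrange per-population results into the output table.

    ``results`` maps population label to either a
    :class:`~continuitest.inference.ContinuityTest`, or to an exception /
    None for a failed fit (emitted as an NA row with status ``failed``).
    ``datasets`` (same keys) supplies the read counts behind the ``cov``
    column; without it cov is NA.
    """
    datasets = datasets or {}
    rows = []
    for pop in sorted(results):
        res = results[pop]
        if isinstance(res, ContinuityTest):
            data = datasets.get(pop)
            rows.append({
                "pop": pop,
                "cov": mean_coverage(data) if data is not None else np.nan,
                "t1": res.full.t1,
                "t2": res.full.t2,
                "lnL": res.full.lnl,
                "t1_cont": res.null.t1,
                "lnL_cont": res.null.lnl,
                "lrt": res.lrt,
                "p_chi2_1df": res.p_chi2_1df,
                "p_mixture": res.p_mixture,
                "status": "ok",
            })
        else:
            rows.append({**{c: np.nan for c in RESULT_COLUMNS}, "pop": pop, "status": "failed"})
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(
    results: dict, path, config: dict | None = None, datasets: dict | None = None
) -> None:
    """Write the results TSV and a structured JSON sidecar.

    ``path`` is the TSV destination; the JSON lands at ``path`` with a
    ``.json`` suffix appended.  The JSON carries the same numbers plus
    the run configuration (seeds, filter counts) supplied in ``config``.
    """
    table = results_table(results, datasets=datasets)
    table.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")
    payload = {
        "populations": {
            row["pop"]: {
                k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in row.items()
                if k != "pop"
            }
            for row in table.to_dict("records")
        },
        "config": config or {},
    }
    validate_results_json(payload)
    with open(f"{path}.json", "w") as fh:
        json.dump(payload, fh, indent=2)
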