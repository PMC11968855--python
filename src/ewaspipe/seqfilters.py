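"""Coverage-based QC of sequencing-derived methylation.

Two input dialects are supported:

* ``bedgraph_panel`` -- targeted short-read output, one row per CpG
  dinucleotide: ``chrom  start  end  pct_methylated  n_meth  n_unmeth``.
* ``bedmethyl_long_read`` -- long-read output, one row per strand per
  cytosine with >= 11 whitespace-separated columns; column 10 is the valid
  coverage and column 11 the percent modified.  Strand records are collapsed
  onto the forward-strand CpG dinucleotide interval by summing counts.

Filtering follows a fixed, audited order: per-entry minimum depth mask,
high-coverage site removal at a quantile of the per-site mean depth,
C->T polymorphism masking, and a minimum-samples-at-minimum-reads
retention rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTable",
    "FilterPolicy",
    "read_coverage",
    "write_coverage",
    "read_bed_mask",
    "merge_coverage",
    "apply_filters",
    "methylation_fraction",
]


@dataclass
class CoverageTable:
    """Per-site, per-sample methylated/total read counts.

    ``sites`` has columns chrom/start/end (0-based half-open, CpG
    dinucleotides are 2 bp); ``meth`` and ``total`` are (n_sites, n_samples)
    integer arrays aligned with ``samples``.
    """

    sites: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray
    build: str = "GRCh38"

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.meth.shape != self.total.shape:
            raise ValueError("meth/total shape mismatch")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count arrays do not match sites x samples")
        if (self.meth < 0).any() or (self.total < 0).any():
            raise ValueError("negative read counts")
        if (self.meth > self.total).any():
            raise ValueError("methylated reads exceed total reads")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> pd.Index:
        s = self.sites
        return pd.Index(
            s["chrom"].astype(str)
            + "-"
            + s["start"].astype(str)
            + "-"
            + s["end"].astype(str)
        )


@dataclass
class FilterPolicy:
    """Site-retention policy; defaults follow the published pipeline."""

    min_doc: int = 2
    high_coverage_quantile: float = 0.99
    snp_mask: pd.DataFrame | None = None
    min_samples: int = 40
    min_reads_platform: int = 10  # 10 for the short-read panel, 5 for long-read
    field_order: tuple[str, ...] = field(
        default=("low_doc_mask", "high_coverage", "snp_mask", "sample_support"),
        repr=False,
    )

    def __post_init__(self) -> None:
        if self.min_doc < 1:
            raise ValueError("min_doc must be >= 1")
        if not 0.0 < self.high_coverage_quantile < 1.0:
            raise ValueError("high_coverage_quantile must be in (0, 1)")
        if self.min_samples < 1 or self.min_reads_platform < 1:
            raise ValueError("min_samples and min_reads_platform must be >= 1")


def _parse_int(tok: str, lineno: int, what: str) -> int:
    try:
        value = int(tok)
    except ValueError:
        raise ValueError(f"line {lineno}: malformed {what} {tok!r}")
    if value < 0 or value > 2**62:
        raise ValueError(f"line {lineno}: coordinate overflow in {what}: {tok!r}")
    return value


def _read_bedgraph_panel(path, sample_id: str) -> CoverageTable:
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    meth: list[int] = []
    total: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            toks = line.split()
            if len(toks) < 6:
                raise ValueError(f"line {lineno}: expected 6 bedGraph columns, got {len(toks)}")
            start = _parse_int(toks[1], lineno, "start")
            end = _parse_int(toks[2], lineno, "end")
            if end <= start:
                raise ValueError(f"line {lineno}: end <= start")
            n_meth = _parse_int(toks[4], lineno, "methylated count")
            n_unmeth = _parse_int(toks[5], lineno, "unmethylated count")
            chroms.append(toks[0])
            starts.append(start)
            ends.append(end)
            meth.append(n_meth)
            total.append(n_meth + n_unmeth)
    sites = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return CoverageTable(
        sites=sites,
        samples=[sample_id],
        meth=np.array(meth, dtype=np.int64).reshape(-1, 1),
        total=np.array(total, dtype=np.int64).reshape(-1, 1),
    )


def _read_bedmethyl_long_read(path, sample_id: str) -> CoverageTable:
    # keyed by (chrom, forward start); strand rows collapsed by summing
    acc: dict[tuple[str, int], list[int]] = {}
    order: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            toks = line.split()
            if len(toks) < 11:
                raise ValueError(
                    f"line {lineno}: expected >= 11 bedMethyl columns, got {len(toks)}"
                )
            start = _parse_int(toks[1], lineno, "start")
            end = _parse_int(toks[2], lineno, "end")
            if end <= start:
                raise ValueError(f"line {lineno}: end <= start")
            strand = toks[5]
            if strand not in {"+", "-", "."}:
                raise ValueError(f"line {lineno}: bad strand {strand!r}")
            valid = _parse_int(toks[9], lineno, "valid coverage")
            try:
                pct = float(toks[10])
            except ValueError:
                raise ValueError(f"line {lineno}: malformed percent modified {toks[10]!r}")
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"line {lineno}: percent modified outside [0, 100]")
            n_meth = int(round(valid * pct / 100.0))
            # reverse-strand C sits one base into the dinucleotide
            fwd_start = start - 1 if strand == "-" else start
            key = (toks[0], fwd_start)
            if key not in acc:
                acc[key] = [0, 0]
                order.append(key)
            acc[key][0] += n_meth
            acc[key][1] += valid
    chroms = [k[0] for k in order]
    starts = [k[1] for k in order]
    sites = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": [s + 2 for s in starts]}
    )
    meth = np.array([acc[k][0] for k in order], dtype=np.int64).reshape(-1, 1)
    total = np.array([acc[k][1] for k in order], dtype=np.int64).reshape(-1, 1)
    return CoverageTable(sites=sites, samples=[sample_id], meth=meth, total=total)


_DIALECTS = {"bedgraph_panel": _read_bedgraph_panel, "bedmethyl_long_read": _read_bedmethyl_long_read}


def read_coverage(path, dialect: str, sample_id: str | None = None) -> CoverageTable:
    """Read one sample's coverage file under the declared dialect."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    if sample_id is None:
        sample_id = str(path)
    return _DIALECTS[dialect](path, sample_id)


def write_coverage(table: CoverageTable, path, dialect: str, sample: str | int = 0) -> None:
    """Write one sample of *table* in canonical form for the dialect.

    Canonical bedMethyl is forward-strand collapsed (one '+' row per CpG);
    ``read(write(x))`` preserves counts exactly and a canonical file
    round-trips byte-identically.
    """
    idx = table.samples.index(sample) if isinstance(sample, str) else int(sample)
    meth = table.meth[:, idx]
    total = table.total[:, idx]
    sites = table.sites
    with open(path, "w") as fh:
        if dialect == "bedgraph_panel":
            for (chrom, start, end), m, t in zip(
                sites.itertuples(index=False), meth, total
            ):
                pct = 100.0 * m / t if t > 0 else 0.0
                fh.write(f"{chrom}\t{start}\t{end}\t{pct:.6f}\t{m}\t{t - m}\n")
        elif dialect == "bedmethyl_long_read":
            for (chrom, start, end), m, t in zip(
                sites.itertuples(index=False), meth, total
            ):
                pct = 100.0 * m / t if t > 0 else 0.0
                score = min(int(t), 1000)
                fh.write(
                    f"{chrom}\t{start}\t{start + 1}\tm\t{score}\t+\t"
                    f"{start}\t{start + 1}\t255,0,0\t{t}\t{pct:.6f}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_bed_mask(path) -> pd.DataFrame:
    """Read a BED3 interval mask (e.g. known C->T polymorphisms)."""
    chroms, starts, ends = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            toks = line.split()
            if len(toks) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 BED columns")
            chroms.append(toks[0])
            starts.append(_parse_int(toks[1], lineno, "start"))
            ends.append(_parse_int(toks[2], lineno, "end"))
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


def merge_coverage(tables: list[CoverageTable]) -> CoverageTable:
    """Merge single-sample tables on the union of intervals (absent = 0 reads)."""
    if not tables:
        raise ValueError("no tables to merge")
    builds = {t.build for t in tables}
    if len(builds) > 1:
        raise ValueError(f"mixed genome builds: {sorted(builds)}")
    keys: dict[tuple[str, int, int], int] = {}
    for t in tables:
        for tup in t.sites.itertuples(index=False):
            key = (tup.chrom, int(tup.start), int(tup.end))
            if key not in keys:
                keys[key] = len(keys)
    n_sites = len(keys)
    samples: list[str] = []
    cols_m, cols_t = [], []
    for t in tables:
        for s_i, sample in enumerate(t.samples):
            m = np.zeros(n_sites, dtype=np.int64)
            tt = np.zeros(n_sites, dtype=np.int64)
            rows = [keys[(tup.chrom, int(tup.start), int(tup.end))] for tup in t.sites.itertuples(index=False)]
            m[rows] = t.meth[:, s_i]
            tt[rows] = t.total[:, s_i]
            samples.append(sample)
            cols_m.append(m)
            cols_t.append(tt)
    ordered = sorted(keys, key=lambda k: (k[0], k[1], k[2]))
    perm = np.array([keys[k] for k in ordered], dtype=np.int64)
    sites = pd.DataFrame(ordered, columns=["chrom", "start", "end"])
    meth = np.stack(cols_m, axis=1)[perm]
    total = np.stack(cols_t, axis=1)[perm]
    return CoverageTable(sites=sites, samples=samples, meth=meth, total=total, build=builds.pop())


def _mask_hits(sites: pd.DataFrame, mask: pd.DataFrame) -> np.ndarray:
    hit = np.zeros(len(sites), dtype=bool)
    for chrom, grp in mask.groupby("chrom"):
        sel = sites["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        s = sites.loc[sel, "start"].to_numpy()
        e = sites.loc[sel, "end"].to_numpy()
        sub = np.zeros(sel.sum(), dtype=bool)
        for ms, me in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            sub |= (s < me) & (e > ms)
        hit[np.flatnonzero(sel)[sub]] = True
    return hit


def apply_filters(
    table: CoverageTable, policy: FilterPolicy
) -> tuple[CoverageTable, pd.DataFrame]:
    """Apply the four retention steps in order; return survivors + audit log.

    Steps: (1) mask per-sample entries below ``min_doc`` (entry masking, not
    site removal); (2) drop sites whose cross-sample mean depth (after step 1)
    is strictly above the ``high_coverage_quantile`` of the site mean-depth
    distribution -- ties at the quantile survive; (3) drop sites overlapping
    the polymorphism mask; (4) keep sites covered by >= ``min_reads_platform``
    reads in >= ``min_samples`` samples.
    """
    n_samples = len(table.samples)
    if policy.min_samples > n_samples:
        raise ValueError(
            f"min_samples={policy.min_samples} exceeds sample count {n_samples}"
        )
    meth = table.meth.copy()
    total = table.total.copy()

    audit_rows = []
    remaining = np.ones(table.n_sites, dtype=bool)

    # 1) entry-level minimum depth mask
    low = total < policy.min_doc
    meth[low] = 0
    total[low] = 0
    audit_rows.append(("low_doc_mask", 0, int(remaining.sum())))

    # 2) high-coverage sites
    mean_doc = total.mean(axis=1)
    cutoff = np.quantile(mean_doc[remaining], policy.high_coverage_quantile)
    drop = remaining & (mean_doc > cutoff)
    remaining &= ~drop
    audit_rows.append(("high_coverage", int(drop.sum()), int(remaining.sum())))

    # 3) polymorphism mask
    if policy.snp_mask is not None and len(policy.snp_mask):
        drop = remaining & _mask_hits(table.sites, policy.snp_mask)
    else:
        drop = np.zeros_like(remaining)
    remaining &= ~drop
    audit_rows.append(("snp_mask", int(drop.sum()), int(remaining.sum())))

    # 4) sample-support retention
    support = (total >= policy.min_reads_platform).sum(axis=1)
    drop = remaining & (support < policy.min_samples)
    remaining &= ~drop
    audit_rows.append(("sample_support", int(drop.sum()), int(remaining.sum())))

    audit = pd.DataFrame(audit_rows, columns=["step", "sites_removed", "sites_remaining"])
    keep = np.flatnonzero(remaining)
    filtered = CoverageTable(
        sites=table.sites.iloc[keep].reset_index(drop=True),
        samples=list(table.samples),
        meth=meth[keep],
        total=total[keep],
        build=table.build,
    )
    for step, removed, left in audit_rows:
        logger.info("seqfilter %-14s removed=%d remaining=%d", step, removed, left)
    return filtered, audit


def methylation_fraction(table: CoverageTable) -> pd.DataFrame:
    """Samples x sites methylation fractions; masked entries become NaN."""
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(table.total > 0, table.meth / np.maximum(table.total, 1), np.nan)
    return pd.DataFrame(frac.T, index=pd.Index(table.samples, name="sample_id"),
                        columns=table.site_ids)
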