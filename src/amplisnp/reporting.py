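"""Summary artifacts: per-region statistics, sharing summaries, VCF output
and text SNP maps.

Densities are printed at 6 decimals (round-half-even). The per-amplicon
coverage statistic pools the per-(variant, carrier) supporting coverages —
i.e. for every validated variant, the number of reads of each carrier that
truly show the alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import DesignError, ExperimentDesign, PanelDef, ReferenceSequence
from .variant_filter import FilterTrace, ValidatedVariant, classify_variant


def snp_density(n_variants: int, insert_length: int) -> float:
    """Variants per insert base, at 6 decimals (round-half-even)."""
    if insert_length <= 0:
        raise DesignError("insert_length must be positive")
    d = Decimal(n_variants) / Decimal(insert_length)
    return float(d.quantize(Decimal("0.000001"), rounding=ROUND_HALF_EVEN))


def _cov_stats(values: Sequence[int]) -> tuple[float, float]:
    if not values:
        return (float("nan"), float("nan"))
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return round(mean, 1), round(sd, 1)


_CLASS_COLS = ("transitions", "transversions", "insertions", "deletions")


def _classify_counts(variants: Iterable[ValidatedVariant]) -> dict[str, int]:
    counts = dict.fromkeys(_CLASS_COLS, 0)
    for v in variants:
        counts[
            {
                "transition": "transitions",
                "transversion": "transversions",
                "insertion": "insertions",
                "deletion": "deletions",
            }[v.classification]
        ] += 1
    return counts


def region_stats(
    validated: Sequence[ValidatedVariant], panel: PanelDef
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-amplicon statistics (with a totals row) and a per-region rollup.

    Multiallelic positions contribute once per validated alternate allele to
    the variant counts; the ``multiallelic`` column counts loci.
    """
    by_amp: dict[int, list[ValidatedVariant]] = {a.index: [] for a in panel}
    for v in validated:
        amp = panel.amplicon_at(v.position)
        if amp is None:
            raise DesignError(
                f"variant at position {v.position} lies outside all amplicon inserts"
            )
        by_amp[amp.index].append(v)
    rows = []
    for a in panel:
        vs = by_amp[a.index]
        coverages = [sup for v in vs for sup in v.supporting.values()]
        mean, sd = _cov_stats(coverages)
        positions = [v.position for v in vs]
        n_multi = sum(
            1 for p in set(positions) if sum(q == p for q in positions) > 1
        )
        rows.append(
            {
                "region": a.region_name,
                "amplicon": a.index,
                "insert_length": a.insert_length,
                "n_variants": len(vs),
                "snps_per_base": snp_density(len(vs), a.insert_length),
                "cov_mean": mean,
                "cov_sd": sd,
                "multiallelic": n_multi,
                **_classify_counts(vs),
            }
        )
    df = pd.DataFrame(rows)
    all_cov = [sup for v in validated for sup in v.supporting.values()]
    t_mean, t_sd = _cov_stats(all_cov)
    totals = {
        "region": "TOTAL",
        "amplicon": 0,
        "insert_length": int(df["insert_length"].sum()),
        "n_variants": int(df["n_variants"].sum()),
        "snps_per_base": snp_density(
            int(df["n_variants"].sum()), int(df["insert_length"].sum())
        ),
        "cov_mean": t_mean,
        "cov_sd": t_sd,
        "multiallelic": int(df["multiallelic"].sum()),
        **{c: int(df[c].sum()) for c in _CLASS_COLS},
    }
    amp_table = pd.concat([df, pd.DataFrame([totals])], ignore_index=True)
    region_rows = []
    for region, g in df.groupby("region", sort=False):
        region_rows.append(
            {
                "region": region,
                "n_amplicons": len(g),
                "insert_length": int(g["insert_length"].sum()),
                "n_variants": int(g["n_variants"].sum()),
                "snps_per_base": snp_density(
                    int(g["n_variants"].sum()), int(g["insert_length"].sum())
                ),
                **{c: int(g[c].sum()) for c in _CLASS_COLS},
            }
        )
    return amp_table, pd.DataFrame(region_rows)


def summarize_panel_table(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute densities and a totals row from a per-amplicon summary
    table (columns insert_length_bp, n_snps, class counts) — the design
    arithmetic of the packaged 20-amplicon panel."""
    df = table.copy()
    df["snps_per_base"] = [
        snp_density(int(n), int(length))
        for n, length in zip(df["n_snps"], df["insert_length_bp"])
    ]
    totals = {
        "region": "TOTAL",
        "amplicon": 0,
        "insert_length_bp": int(df["insert_length_bp"].sum()),
        "n_snps": int(df["n_snps"].sum()),
        "snps_per_base": snp_density(
            int(df["n_snps"].sum()), int(df["insert_length_bp"].sum())
        ),
        "multiallelic": int(df["multiallelic"].sum()),
        "transitions": int(df["transitions"].sum()),
        "transversions": int(df["transversions"].sum()),
        "indels": int(df["indels"].sum()),
    }
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


# ---------------------------------------------------------------------------
# Population sharing
# ---------------------------------------------------------------------------


@dataclass
class SharingSummary:
    """How widely each validated variant is shared across sampling
    locations."""

    n_locations: int
    location_counts: dict[tuple[int, str, str], int] = field(default_factory=dict)

    def _fraction(self, predicate) -> float:
        if not self.location_counts:
            return 0.0
        n = sum(1 for c in self.location_counts.values() if predicate(c))
        return round(100.0 * n / len(self.location_counts), 1)

    @property
    def pct_single_location(self) -> float:
        return self._fraction(lambda c: c == 1)

    @property
    def pct_all_locations(self) -> float:
        return self._fraction(lambda c: c == self.n_locations)

    @property
    def pct_under_10_locations(self) -> float:
        return self._fraction(lambda c: c < 10)

    @property
    def pct_over_half_locations(self) -> float:
        return self._fraction(lambda c: c > 0.5 * self.n_locations)


def sharing_summary(
    validated: Sequence[ValidatedVariant], design: ExperimentDesign
) -> SharingSummary:
    """Count, per variant, the sampling locations its carriers span."""
    loc_of = {s.sample_id: s.location_id for s in design.samples}
    all_locations = sorted(set(loc_of.values()))
    summary = SharingSummary(n_locations=len(all_locations))
    for v in validated:
        locs = set()
        for carrier in v.carriers:
            if carrier not in loc_of:
                raise DesignError(f"carrier {carrier} has no sampling location")
            locs.add(loc_of[carrier])
        summary.location_counts[v.key] = len(locs)
    return summary


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_CLASS = {
    "transition": "TS",
    "transversion": "TV",
    "insertion": "INS",
    "deletion": "DEL",
}
_CLASS_FROM_VCF = {v: k for k, v in _VCF_CLASS.items()}


def _vcf_record_alleles(
    v: ValidatedVariant, reference: ReferenceSequence
) -> tuple[int, str, str]:
    """(POS, REF, ALT) in VCF anchored-base convention."""
    if v.kind == "substitution":
        if reference.bases[v.position - 1] != v.ref_allele:
            raise DesignError(
                f"variant at {v.position}: ref allele {v.ref_allele} does not "
                f"match reference base {reference.bases[v.position - 1]}"
            )
        return v.position, v.ref_allele, v.alt_allele
    if v.kind == "deletion":
        pos = v.position - 1
        anchor = reference.bases[pos - 1]
        if reference.bases[v.position - 1 : v.position - 1 + len(v.ref_allele)] != v.ref_allele:
            raise DesignError(f"deletion at {v.position}: alleles inconsistent with reference")
        return pos, anchor + v.ref_allele, anchor
    anchor = reference.bases[v.position - 1]
    return v.position, anchor, anchor + v.alt_allele


def write_vcf(
    validated: Sequence[ValidatedVariant],
    reference: ReferenceSequence,
    path: str | Path,
) -> None:
    """Write validated variants as VCF 4.2, deterministically ordered by
    position; alternates sharing (POS, REF) are emitted as one multiallelic
    record with comma-separated ALT alleles."""
    grouped: dict[tuple[int, str], list[ValidatedVariant]] = {}
    for v in sorted(validated, key=lambda v: (v.position, v.alt_allele, v.ref_allele)):
        pos, ref, alt = _vcf_record_alleles(v, reference)
        grouped.setdefault((pos, ref), []).append(v)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference.id},length={reference.length}>\n")
        fh.write('##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of carrier samples">\n')
        fh.write('##INFO=<ID=TYPE,Number=A,Type=String,Description="Variant class">\n')
        fh.write('##INFO=<ID=MDP,Number=A,Type=Float,Description="Mean supporting reads per carrier">\n')
        fh.write('##INFO=<ID=CARRIERS,Number=A,Type=String,Description="Carrier sample ids (| separated)">\n')
        fh.write('##INFO=<ID=SUP,Number=A,Type=String,Description="Per-carrier supporting reads (| separated)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for (pos, ref), group in sorted(grouped.items()):
            alts, types, mdps, carriers, sups = [], [], [], [], []
            all_carriers = set()
            for v in group:
                _, _, alt = _vcf_record_alleles(v, reference)
                alts.append(alt)
                types.append(_VCF_CLASS[v.classification])
                mdps.append(
                    f"{np.mean([v.supporting[c] for c in v.carriers]):.2f}"
                )
                carriers.append("|".join(v.carriers))
                sups.append("|".join(str(v.supporting[c]) for c in v.carriers))
                all_carriers.update(v.carriers)
            info = (
                f"NS={len(all_carriers)};TYPE={','.join(types)};"
                f"MDP={','.join(mdps)};CARRIERS={','.join(carriers)};"
                f"SUP={','.join(sups)}"
            )
            fh.write(
                f"{reference.id}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t{info}\n"
            )


def read_vcf(path: str | Path, reference: ReferenceSequence) -> list[ValidatedVariant]:
    """Read a VCF written by :func:`write_vcf` back into validated-variant
    records (evidence is not round-tripped; carriers and per-carrier support
    are)."""
    import pysam

    out: list[ValidatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            carriers_field = rec.info["CARRIERS"]
            sup_field = rec.info["SUP"]
            if isinstance(carriers_field, str):
                carriers_field = (carriers_field,)
                sup_field = (sup_field,)
            for alt, carriers_str, sup_str in zip(rec.alts, carriers_field, sup_field):
                ref = rec.ref
                pos = rec.pos
                # undo the anchored-base encoding
                if len(ref) == 1 and len(alt) == 1:
                    position, ref_allele, alt_allele = pos, ref, alt
                elif len(ref) > len(alt):
                    position, ref_allele, alt_allele = pos + 1, ref[1:], ""
                else:
                    position, ref_allele, alt_allele = pos, "", alt[1:]
                carriers = tuple(carriers_str.split("|"))
                supporting = {
                    c: int(s) for c, s in zip(carriers, sup_str.split("|"))
                }
                v = ValidatedVariant(
                    position=position,
                    ref_allele=ref_allele,
                    alt_allele=alt_allele,
                    kind="substitution"
                    if ref_allele and alt_allele
                    else ("insertion" if alt_allele else "deletion"),
                    classification="",
                    carriers=carriers,
                    supporting=supporting,
                    evidence={},
                )
                v.classification = classify_variant(v)
                out.append(v)
    from .variant_filter import group_multiallelic

    out.sort(key=lambda v: (v.position, v.alt_allele, v.ref_allele))
    group_multiallelic(out)
    return out


# ---------------------------------------------------------------------------
# SNP maps and run reports
# ---------------------------------------------------------------------------


def snp_map(
    validated: Sequence[ValidatedVariant],
    panel: PanelDef,
    prior_panel: Optional[Iterable[tuple[int, str, str]]] = None,
) -> pd.DataFrame:
    """Ordered per-region position map with a novel/known flag against an
    optional prior variant panel."""
    prior = set(prior_panel) if prior_panel is not None else set()
    rows = []
    for v in sorted(validated, key=lambda v: v.position):
        amp = panel.amplicon_at(v.position)
        rows.append(
            {
                "region": amp.region_name if amp else "NA",
                "amplicon": amp.index if amp else 0,
                "position": v.position,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "classification": v.classification,
                "status": "known" if v.key in prior else "novel",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["region", "amplicon", "position", "ref", "alt", "classification", "status"],
    )


def load_prior_panel(path: str | Path) -> set[tuple[int, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        (int(r["position"]), str(r["ref"]) if not pd.isna(r["ref"]) else "",
         str(r["alt"]) if not pd.isna(r["alt"]) else "")
        for _, r in df.iterrows()
    }


def write_filter_trace(trace: FilterTrace, path: str | Path) -> None:
    rows = [
        {"stage": "raw_candidates", "remaining": trace.n_raw},
        {"stage": "after_artifact_rejection", "remaining": trace.n_after_artifact},
        {"stage": "after_both_strand", "remaining": trace.n_after_both_strand},
        {"stage": "after_support", "remaining": trace.n_after_support},
        {"stage": "validated", "remaining": trace.n_validated},
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sharing_summary(summary: SharingSummary, path: str | Path) -> None:
    rows = [
        {"category": "n_locations", "value": summary.n_locations},
        {"category": "pct_single_location", "value": summary.pct_single_location},
        {"category": "pct_all_locations", "value": summary.pct_all_locations},
        {"category": "pct_under_10_locations", "value": summary.pct_under_10_locations},
        {"category": "pct_over_half_locations", "value": summary.pct_over_half_locations},
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
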