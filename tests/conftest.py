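"""Shared fixtures: brute-force oracles kept independent of the streaming code."""

from __future__ import annotations

import pytest

from wgspipe.merge import GenotypeRow
from wgspipe.soapsnp import (
    IUPAC_DIPLOID,
    FilterCriteria,
    SecondBaseRule,
    SnpRecord,
)


def _oracle_passes(rec: SnpRecord, criteria: FilterCriteria) -> bool:
    """Filter re-stated from the quality-SNP definition, not the implementation."""
    import math

    cutoff = math.floor(-10 * math.log10(1 - criteria.confidence) + 1e-9)
    if not rec.quality > cutoff:
        return False
    if rec.best_unique_count < criteria.min_unique_reads:
        return False
    need_second = True
    if criteria.second_base_rule is SecondBaseRule.HET_ONLY:
        pair = IUPAC_DIPLOID.get(rec.consensus)
        need_second = pair is None or pair[0] != pair[1]
    if need_second and rec.second_unique_count < criteria.min_unique_reads:
        return False
    return True


def brute_force_merge(
    all_records: list[list[SnpRecord]],
    criteria: FilterCriteria,
    missing_code: str = "NN",
) -> list[GenotypeRow]:
    """Load everything, filter, union positions, sort — the slow reference.

    Mirrors the merge contract with none of the streaming machinery: the
    expected output for any fixture small enough to hold in memory.
    """
    n = len(all_records)
    by_pos: dict[int, dict[int, SnpRecord]] = {}
    for i, records in enumerate(all_records):
        for rec in records:
            by_pos.setdefault(rec.pos, {})[i] = rec
    rows: list[GenotypeRow] = []
    for pos in sorted(by_pos):
        group = by_pos[pos]
        codes = [missing_code] * n
        any_passing = False
        chrom = ref = None
        for i, rec in group.items():
            chrom, ref = rec.chrom, rec.ref_base
            if not _oracle_passes(rec, criteria):
                continue
            pair = IUPAC_DIPLOID.get(rec.consensus)
            if pair is None:
                continue
            codes[i] = "".join(sorted(pair))
            any_passing = True
        if any_passing:
            rows.append(
                GenotypeRow(
                    chrom=chrom, pos=pos, ref_base=ref, genotype_codes=tuple(codes)
                )
            )
    return rows


@pytest.fixture
def merge_oracle():
    return brute_force_merge
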