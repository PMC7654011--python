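"""Instrument selection: filters, greedy clumping, proxy search."""

import numpy as np
import pytest

from mrflow import (
    DataError,
    PanelLookupError,
    clump,
    filter_maf,
    filter_significant,
    find_proxy,
)

from conftest import make_panel, make_summary, make_variant


# ---------------------------------------------------------------------- filters

def test_significance_filter_is_strict_and_counts_removals():
    s = make_summary(
        [make_variant("rs1", pval=1e-9), make_variant("rs2", pos=2000, pval=1e-7)]
    )
    kept = filter_significant(s, 5e-8)
    assert kept.rsids() == ["rs1"]
    assert kept.provenance == {"input": 2, "not_significant": 1}


def test_significance_filter_matches_brute_force_scan(rng):
    pvals = 10 ** rng.uniform(-12, 0, size=100)
    s = make_summary(
        [make_variant(f"rs{i}", pos=1000 * i, pval=float(p)) for i, p in enumerate(pvals)]
    )
    kept = filter_significant(s, 5e-8)
    expected = sorted(r.rsid for r in s.records.values() if r.pval < 5e-8)
    assert sorted(kept.rsids()) == expected
    assert len(kept) + kept.provenance["not_significant"] == len(s)


@pytest.mark.parametrize(
    "eaf,retained", [(0.005, False), (0.995, False), (0.01, True), (0.3, True)]
)
def test_maf_filter_symmetric_with_strict_inequality(eaf, retained):
    instr = filter_significant(make_summary([make_variant(eaf=eaf)]), 0.5)
    out = filter_maf(instr, 0.01)
    assert (len(out) == 1) is retained


def test_missing_eaf_retained_and_flagged_by_default_removed_in_strict_mode():
    instr = filter_significant(make_summary([make_variant(eaf=None)]), 0.5)
    out = filter_maf(instr, 0.01)
    assert out.rsids() == ["rs1"] and out.flags["maf_missing"] == ["rs1"]
    strict = filter_maf(instr, 0.01, strict_missing=True)
    assert len(strict) == 0


# --------------------------------------------------------------------- clumping

def brute_force_clump(records, panel, r2_thresh, window_kb):
    """Independent re-derivation of the greedy rule for oracle comparison."""
    pool = [r for r in records if r.rsid in panel]
    pool.sort(key=lambda r: (r.pval, r.rsid))
    kept = []
    while pool:
        index = pool.pop(0)
        kept.append(index)
        ci, pi = panel.location(index.rsid)
        survivors = []
        for r in pool:
            cj, pj = panel.location(r.rsid)
            linked = (
                cj == ci
                and abs(pj - pi) <= window_kb * 1000
                and panel.r2(index.rsid, r.rsid) > r2_thresh
            )
            if not linked:
                survivors.append(r)
        pool = survivors
    return [r.rsid for r in kept]


def _block_panel_and_records(rng, n=20):
    """Random SNPs in LD blocks of 4 on two chromosomes."""
    rows, pairs, recs = [], {}, []
    for i in range(n):
        rsid = f"rs{i:03d}"
        chrom = "1" if i < n // 2 else "2"
        pos = 10_000 + (i % (n // 2)) * 3_000
        rows.append((rsid, chrom, pos))
        recs.append(
            make_variant(rsid, chrom=chrom, pos=pos, pval=float(10 ** rng.uniform(-12, -4)))
        )
    for i in range(n):
        for j in range(i + 1, n):
            if rows[i][1] == rows[j][1] and (i // 4) == (j // 4):
                pairs[(rows[i][0], rows[j][0])] = float(rng.uniform(0, 1))
    return make_panel(rows, pairs), recs


def test_clump_keeps_lower_p_of_linked_pair():
    panel = make_panel([("rsA", "1", 1000), ("rsB", "1", 6000)], {("rsA", "rsB"): 0.5})
    s = make_summary(
        [
            make_variant("rsA", pos=1000, pval=1e-10),
            make_variant("rsB", pos=6000, pval=1e-9),
        ]
    )
    out = clump(filter_significant(s, 0.5), panel, 0.001, 10)
    assert out.rsids() == ["rsA"]
    assert out.provenance["clumped_away"] == 1


def test_clump_ignores_r2_across_chromosomes():
    panel = make_panel([("rsA", "1", 1000), ("rsB", "2", 1000)], {("rsA", "rsB"): 0.99})
    s = make_summary(
        [
            make_variant("rsA", pval=1e-10),
            make_variant("rsB", chrom="2", pval=1e-9),
        ]
    )
    out = clump(filter_significant(s, 0.5), panel, 0.001, 10_000)
    assert sorted(out.rsids()) == ["rsA", "rsB"]


def test_clump_removes_snps_absent_from_panel():
    panel = make_panel([("rsA", "1", 1000)])
    s = make_summary([make_variant("rsA", pval=1e-10), make_variant("rsZ", pos=2, pval=1e-11)])
    out = clump(filter_significant(s, 0.5), panel, 0.001, 10_000)
    assert out.rsids() == ["rsA"]
    assert out.provenance["absent_from_panel"] == 1


def test_clump_matches_brute_force_oracle_on_random_block_panels(rng):
    for _ in range(50):
        panel, recs = _block_panel_and_records(rng)
        instr = filter_significant(make_summary(recs), 0.5)
        out = clump(instr, panel, 0.001, 10_000)
        assert out.rsids() == brute_force_clump(recs, panel, 0.001, 10_000)
        # pairwise independence of the retained set
        for a in out.records:
            for b in out.records:
                ca, pa = panel.location(a.rsid)
                cb, pb = panel.location(b.rsid)
                if a.rsid < b.rsid and ca == cb and abs(pa - pb) <= 10_000_000:
                    assert panel.r2(a.rsid, b.rsid) <= 0.001


def test_clump_invariant_to_input_row_order(rng):
    panel, recs = _block_panel_and_records(rng)
    instr1 = filter_significant(make_summary(recs), 0.5)
    instr2 = filter_significant(make_summary(list(reversed(recs))), 0.5)
    assert clump(instr1, panel, 0.001, 10_000).rsids() == clump(
        instr2, panel, 0.001, 10_000
    ).rsids()


# ----------------------------------------------------------------------- proxies

def _proxy_setup():
    panel = make_panel(
        [("rsT", "1", 100_000), ("rsP1", "1", 110_000), ("rsP2", "1", 120_000),
         ("rsP3", "1", 130_000), ("rsFar", "1", 900_000)],
        {("rsP1", "rsT"): 0.85, ("rsP2", "rsT"): 0.92, ("rsP3", "rsT"): 0.81,
         ("rsFar", "rsT"): 0.99},
    )
    outcome = make_summary(
        [
            make_variant("rsP1", pos=110_000, beta=0.01),
            make_variant("rsP2", pos=120_000, beta=0.02),
            make_variant("rsP3", pos=130_000, beta=0.03),
            make_variant("rsFar", pos=900_000, beta=0.04),
        ],
        unit="SD",
    )
    return panel, outcome


def test_proxy_picks_highest_r2_within_window():
    panel, outcome = _proxy_setup()
    hit = find_proxy("rsT", outcome, panel, r2_min=0.8, window_kb=250)
    assert hit.rsid == "rsP2"  # r2 = 0.92 beats 0.85 and 0.81; rsFar outside window


def test_target_present_in_outcome_is_its_own_proxy():
    panel, outcome = _proxy_setup()
    outcome.add(make_variant("rsT", pos=100_000, beta=0.09))
    assert find_proxy("rsT", outcome, panel).rsid == "rsT"


def test_no_candidate_above_threshold_returns_none():
    panel, outcome = _proxy_setup()
    assert find_proxy("rsT", outcome, panel, r2_min=0.95, window_kb=250) is None


def test_target_absent_from_panel_is_lookup_error():
    panel, outcome = _proxy_setup()
    with pytest.raises(PanelLookupError, match="rsQ"):
        find_proxy("rsQ", outcome, panel)


# -------------------------------------------------------------------- LD panel

def test_panel_r2_is_symmetric_reflexive_and_bounded():
    panel = make_panel([("a", "1", 1), ("b", "1", 2)], {("a", "b"): 0.4})
    assert panel.r2("a", "a") == 1.0
    assert panel.r2("a", "b") == panel.r2("b", "a") == 0.4
    with pytest.raises(DataError):
        make_panel([("a", "1", 1), ("b", "1", 2)], {("a", "b"): 1.4})


def test_panel_round_trips_through_disk(tmp_path):
    panel = make_panel([("a", "1", 1), ("b", "2", 5)], {("a", "b"): 0.25})
    panel.write(tmp_path / "v.tsv", tmp_path / "p.tsv")
    back = type(panel).read(tmp_path / "v.tsv", tmp_path / "p.tsv")
    assert back.r2("a", "b") == 0.25 and back.location("b") == ("2", 5)
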