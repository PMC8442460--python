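"""SV phasing from tagged supporting reads and conflict counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasekit import simulate as sim
from phasekit.sv_phaser import (
    SVPhasingEvidence,
    SVPhasingParams,
    build_tag_interval_index,
    collect_sv_evidence,
    decide_phase,
    phase_sv_set,
)
from phasekit.variant_io import HaplotagRecord, VariantRecord


def tag(name, hp, ps, start=0, end=10_000):
    return HaplotagRecord(name, "chrT", start, end, hp, ps)


def sv(support=("r1", "r2", "r3"), gt=(0, 1), sv_type="DEL", pos=500, sv_len=-100):
    return VariantRecord(
        chrom="chrT", pos=pos, ref="N", alt=f"<{sv_type}>", gt=gt,
        sv_type=sv_type, sv_len=sv_len, supporting_reads=tuple(support),
    )


class TestCollectEvidence:
    def test_unanimous_support(self):
        tags = {f"r{i}": tag(f"r{i}", 1, 9) for i in (1, 2, 3)}
        ev = collect_sv_evidence(sv(), tags)
        assert (ev.hp1_count, ev.hp2_count, ev.conflict_count, ev.dominant_ps) == (3, 0, 0, 9)

    def test_minority_haplotype_counts_as_conflict(self):
        tags = {"r1": tag("r1", 1, 9), "r2": tag("r2", 2, 9), "r3": tag("r3", 1, 9)}
        ev = collect_sv_evidence(sv(), tags)
        assert (ev.hp1_count, ev.hp2_count, ev.conflict_count) == (2, 1, 1)

    def test_cross_ps_tie_breaks_to_smaller_and_counts_conflict(self):
        tags = {"r1": tag("r1", 1, 9), "r2": tag("r2", 1, 13)}
        ev = collect_sv_evidence(sv(support=("r1", "r2")), tags)
        assert ev.dominant_ps == 9 and ev.other_ps_count == 1 and ev.conflict_count == 1

    def test_untagged_supporting_reads_ignored(self):
        tags = {"r1": tag("r1", 2, 9)}
        ev = collect_sv_evidence(sv(), tags)
        assert ev.tagged_reads == 1 and ev.hp2_count == 1

    def test_no_tagged_reads_is_empty_evidence_not_error(self):
        ev = collect_sv_evidence(sv(), {})
        assert ev.tagged_reads == 0 and ev.dominant_ps is None and ev.conflict_count == 0

    def test_duplicate_support_names_counted_once(self):
        tags = {"r1": tag("r1", 1, 9)}
        ev = collect_sv_evidence(sv(support=("r1", "r1")), tags)
        assert ev.tagged_reads == 1

    def test_evidence_invariant_enforced(self):
        with pytest.raises(ValueError):
            SVPhasingEvidence("c", 1, "DEL", tagged_reads=3, hp1_count=1, hp2_count=1,
                              other_ps_count=0, dominant_ps=9, conflict_count=1)


class TestOverlapFallback:
    def test_breakpoint_containment(self):
        # DEL at pos 500 (svlen 100): both breakpoints 499 and 599 must be covered
        tags = [tag("a", 1, 9, 400, 700), tag("b", 1, 9, 550, 900), tag("c", 2, 9, 0, 450)]
        index = build_tag_interval_index(tags)
        ev = collect_sv_evidence(sv(support=()), {t.read_name: t for t in tags}, index)
        assert ev.tagged_reads == 1 and ev.hp1_count == 1  # only 'a' spans both

    def test_insertion_uses_single_breakpoint(self):
        tags = [tag("a", 2, 9, 400, 520), tag("b", 1, 9, 550, 900)]
        index = build_tag_interval_index(tags)
        rec = sv(support=(), sv_type="INS", sv_len=300)
        ev = collect_sv_evidence(rec, {t.read_name: t for t in tags}, index)
        assert ev.tagged_reads == 1 and ev.hp2_count == 1


class TestDecidePhase:
    def test_clean_het_is_phased_on_majority_haplotype(self):
        tags = {f"r{i}": tag(f"r{i}", 1, 9) for i in (1, 2, 3)}
        rec = decide_phase(collect_sv_evidence(sv(), tags), sv())
        assert rec.phased and rec.gt == (1, 0) and rec.ps == 9 and rec.conflict == 0

    def test_majority_hp2_gets_alt_on_haplotype2(self):
        tags = {f"r{i}": tag(f"r{i}", 2, 9) for i in (1, 2, 3)}
        rec = decide_phase(collect_sv_evidence(sv(), tags), sv())
        assert rec.phased and rec.gt == (0, 1)

    def test_one_conflict_blocks_at_default_threshold_but_not_at_two(self):
        tags = {"r1": tag("r1", 1, 9), "r2": tag("r2", 2, 9), "r3": tag("r3", 1, 9)}
        ev = collect_sv_evidence(sv(), tags)
        strict = decide_phase(ev, sv(), SVPhasingParams(conflict_threshold=0))
        assert not strict.phased and strict.conflict == 1
        relaxed = decide_phase(ev, sv(), SVPhasingParams(conflict_threshold=2))
        assert relaxed.phased and relaxed.gt == (1, 0) and relaxed.conflict == 1

    def test_haplotype_tie_never_phases(self):
        tags = {f"r{i}": tag(f"r{i}", 1 + i % 2, 9) for i in range(4)}
        ev = collect_sv_evidence(sv(support=tuple(tags)), tags)
        rec = decide_phase(ev, sv(support=tuple(tags)), SVPhasingParams(conflict_threshold=99))
        assert not rec.phased

    def test_homozygous_sv_passes_through_with_conflict_annotation(self):
        tags = {f"r{i}": tag(f"r{i}", 1, 9) for i in (1, 2, 3)}
        hom = sv(gt=(1, 1))
        rec = decide_phase(collect_sv_evidence(hom, tags), hom)
        assert not rec.phased and rec.gt == (1, 1) and rec.conflict == 0

    def test_min_tagged_reads_gate(self):
        tags = {"r1": tag("r1", 1, 9)}
        ev = collect_sv_evidence(sv(support=("r1",)), tags)
        rec = decide_phase(ev, sv(support=("r1",)), SVPhasingParams(min_tagged_reads=2))
        assert not rec.phased and rec.conflict == 0


class TestPhaseSet:
    def test_empty_input_empty_summary(self):
        records, summary = phase_sv_set([], {})
        assert records == [] and summary.n_het == 0 and summary.phased_pct == 0.0

    def test_per_type_percentages(self):
        tags = {}
        svs = []
        for i in range(4):
            names = tuple(f"d{i}_{j}" for j in range(3))
            hps = (1, 1, 1) if i < 3 else (1, 2, 1)  # last DEL has one conflict
            for n, h in zip(names, hps):
                tags[n] = tag(n, h, 9)
            svs.append(sv(support=names, pos=100 + i))
        _, at0 = phase_sv_set(svs, tags, SVPhasingParams(conflict_threshold=0))
        _, at2 = phase_sv_set(svs, tags, SVPhasingParams(conflict_threshold=2))
        assert at0.per_type["DEL"]["phased_pct"] == 75.0
        assert at2.per_type["DEL"]["phased_pct"] == 100.0

    def test_homozygous_excluded_from_denominator(self):
        tags = {"r1": tag("r1", 1, 9), "r2": tag("r2", 1, 9), "r3": tag("r3", 1, 9)}
        records = [sv(), sv(gt=(1, 1), pos=600)]
        _, summary = phase_sv_set(records, tags)
        assert summary.n_het == 1 and summary.n_het_phased == 1

    def test_conflict_emitted_on_every_record(self, truth, reads):
        _, read_df = reads
        svs, _ = sim.simulate_svs(truth, read_df, n_sv=25, het_fraction=0.6,
                                  n_conflict_reads=1, seed=5)
        records, _ = phase_sv_set(svs, _tags_from(read_df))
        assert all(r.conflict is not None for r in records)

    def test_zero_noise_phasing_is_exact(self, truth, reads):
        _, read_df = reads
        svs, sv_truth = sim.simulate_svs(truth, read_df, n_sv=40, seed=6)
        records, summary = phase_sv_set(svs, _tags_from(read_df))
        assert summary.phased_pct == 100.0
        for rec, info in zip(records, sv_truth):
            assert rec.ps == info["ps"]
            assert rec.gt == ((1, 0) if info["hp"] == 1 else (0, 1))

    def test_phased_fraction_monotone_in_threshold(self, truth, reads):
        _, read_df = reads
        rng = np.random.default_rng(8)
        for fixture_seed in rng.integers(0, 2**31, size=10):
            svs, _ = sim.simulate_svs(truth, read_df, n_sv=20,
                                      n_conflict_reads=int(fixture_seed % 3),
                                      seed=int(fixture_seed))
            fractions = []
            for c in (0, 1, 2, 5):
                _, summary = phase_sv_set(svs, _tags_from(read_df),
                                          SVPhasingParams(conflict_threshold=c))
                fractions.append(summary.phased_pct)
            assert fractions == sorted(fractions)


def _tags_from(read_df):
    tagged = read_df[read_df.tagged]
    return {
        row.read_name: HaplotagRecord(row.read_name, row.chrom, row.start,
                                      row.end, int(row.hp), int(row.ps))
        for row in tagged.itertuples(index=False)
    }


def brute_force_conflicts(support, tags):
    """Independent recount: dominant PS by vote, conflicts = everything
    not in the largest same-(PS, HP) group of the dominant PS."""
    tagged = [tags[r] for r in dict.fromkeys(support) if r in tags]
    if not tagged:
        return 0
    ps_votes = {}
    for t in tagged:
        ps_votes[t.ps] = ps_votes.get(t.ps, 0) + 1
    best = max(ps_votes.values())
    dominant = min(ps for ps, v in ps_votes.items() if v == best)
    majority = max(
        sum(1 for t in tagged if t.ps == dominant and t.hp == hp) for hp in (1, 2)
    )
    return len(tagged) - majority


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 19), st.sampled_from([1, 2]), st.sampled_from([9, 13, 20])),
        min_size=0, max_size=12,
    )
)
def test_conflict_count_matches_brute_force(assignments):
    """Property: conflict_count equals an independent recount for
    arbitrary support/tag configurations."""
    tags = {}
    support = []
    for i, (read_id, hp, ps) in enumerate(assignments):
        name = f"r{read_id}"
        support.append(name)
        tags.setdefault(name, tag(name, hp, ps))
    record = sv(support=tuple(support))
    ev = collect_sv_evidence(record, tags)
    assert ev.conflict_count == brute_force_conflicts(support, tags)
    assert ev.tagged_reads == ev.hp1_count + ev.hp2_count + ev.other_ps_count
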