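"""Dataset curation: loading, validation, deduplication, reversibility
augmentation, splitting and summary statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from priddg import (
    MutationDataset,
    MutationRecord,
    SplitSpec,
    compute_stats,
    deduplicate_and_resolve,
    load_dataset,
    random_split,
    reverse_augment,
)
from priddg.dataset import MutationValidationError, parse_mutation_token


def _forward(cid, wt, pos, mut, ddg, chain="A"):
    return MutationRecord(cid, chain, wt, pos, mut, ddg)


def _dataset_of(n, seed=0):
    """n forward records on one long synthetic chain."""
    rng = np.random.default_rng(seed)
    seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=n + 10))
    records = []
    for i in range(n):
        wt = seq[i]
        mut = "A" if wt != "A" else "G"
        records.append(MutationRecord("1SYN", "A", wt, i + 1, mut,
                                      float(rng.normal())))
    return MutationDataset(records, {"1SYN_A": seq})


# -- loading -----------------------------------------------------------------

def test_load_dataset_parses_token_row(tmp_path):
    # 1AUD chain A, Q53E with ΔΔG 6.60 — sequence here is a synthetic
    # stand-in carrying Q at position 53
    seq = "M" * 52 + "Q" + "R" * 20
    (tmp_path / "seqs.fasta").write_text(f">1AUD_A\n{seq}\n")
    (tmp_path / "muts.csv").write_text(
        "complex_id,chain,mutation,ddg\n1AUD,A,Q53E,6.60\n"
    )
    ds = load_dataset(tmp_path / "muts.csv", tmp_path / "seqs.fasta")
    (rec,) = ds.records
    assert (rec.wt_residue, rec.position, rec.mut_residue) == ("Q", 53, "E")
    assert rec.ddg == pytest.approx(6.60)
    assert rec.direction == "forward"


def test_load_dataset_preserves_row_count(tmp_path):
    seq = "QWERTYIPASDFGHKLCVNM" * 3
    (tmp_path / "seqs.fasta").write_text(f">1ABC_A\n{seq}\n")
    rows = ["complex_id,chain,mutation,ddg"]
    for i, pos in enumerate([1, 5, 9]):
        rows.append(f"1ABC,A,{seq[pos-1]}{pos}G,{i * 0.5}")
    (tmp_path / "m.csv").write_text("\n".join(rows) + "\n")
    ds = load_dataset(tmp_path / "m.csv", {"1ABC_A": seq})
    assert len(ds) == 3
    assert all(r.direction == "forward" for r in ds.records)


@pytest.mark.parametrize(
    "token,msg",
    [("Q53Q", "identity"), ("Q53B", "unknown residue"), ("53E", "malformed"),
     ("QxE", "malformed")],
)
def test_load_dataset_rejects_bad_tokens(tmp_path, token, msg):
    (tmp_path / "m.csv").write_text(
        f"complex_id,chain,mutation,ddg\n1ABC,A,{token},1.0\n"
    )
    with pytest.raises(MutationValidationError, match=msg):
        load_dataset(tmp_path / "m.csv", {"1ABC_A": "Q" * 60})


def test_load_dataset_validates_against_sequence(tmp_path):
    (tmp_path / "m.csv").write_text("complex_id,chain,mutation,ddg\n1ABC,A,Q5E,1.0\n")
    with pytest.raises(MutationValidationError, match="expected Q"):
        load_dataset(tmp_path / "m.csv", {"1ABC_A": "KKKKKKK"})
    with pytest.raises(MutationValidationError, match="beyond sequence length"):
        load_dataset(tmp_path / "m.csv", {"1ABC_A": "KQK"})
    with pytest.raises(MutationValidationError, match="no sequence registered"):
        load_dataset(tmp_path / "m.csv", {"9ZZZ_A": "KKKKQKK"})


def test_parse_mutation_token_roundtrip():
    assert parse_mutation_token("G52A") == ("G", 52, "A")
    assert parse_mutation_token("q53e") == ("Q", 53, "E")


# -- deduplication -----------------------------------------------------------

def test_dedup_collapses_exact_duplicates():
    a = _forward("1A", "Q", 5, "E", 1.0)
    assert deduplicate_and_resolve([a, a]) == [a]


def test_dedup_drops_conflicting_measurements():
    a = _forward("1A", "Q", 5, "E", 1.0)
    b = _forward("1A", "Q", 5, "E", 2.0)
    assert deduplicate_and_resolve([a, b], tolerance=1e-6) == []


def test_dedup_keeps_distinct_mutations():
    a = _forward("1A", "Q", 5, "E", 1.0)
    b = _forward("1A", "K", 9, "A", -0.5)
    assert deduplicate_and_resolve([a, a, b]) == [a, b]


def test_dedup_within_tolerance_keeps_first():
    a = _forward("1A", "Q", 5, "E", 1.0)
    b = _forward("1A", "Q", 5, "E", 1.0 + 1e-8)
    assert deduplicate_and_resolve([a, b]) == [a]


# -- reversibility augmentation ----------------------------------------------

def test_reverse_augment_negates_and_swaps(toy_dataset):
    out = reverse_augment(toy_dataset)
    assert len(out) == 2 * len(toy_dataset)
    fwd = toy_dataset.records[0]
    rev = out.records[len(toy_dataset)]
    assert (rev.wt_residue, rev.mut_residue) == (fwd.mut_residue, fwd.wt_residue)
    assert rev.ddg == -fwd.ddg
    assert rev.direction == "reverse"
    # reverse context carries the forward mutant residue at the site
    assert out.sequence_for(rev)[rev.position - 1] == rev.wt_residue
    out.validate()


def test_reverse_augment_zero_ddg():
    ds = MutationDataset([_forward("1A", "K", 3, "A", 0.0)], {"1A_A": "GGKGG"})
    out = reverse_augment(ds)
    assert out.records[1].ddg == 0.0


def test_reverse_augment_doubles_315_to_630():
    ds = _dataset_of(315)
    assert len(reverse_augment(ds)) == 630


def test_reverse_augment_rejects_double_augmentation(toy_dataset):
    once = reverse_augment(toy_dataset)
    with pytest.raises(MutationValidationError, match="double augmentation"):
        reverse_augment(once)


@given(st.lists(st.floats(-10, 10, allow_nan=False, width=32), min_size=1, max_size=60))
def test_augmentation_is_involution_on_labels(ddgs):
    """Negating every reverse label recovers its forward partner exactly."""
    ds = _dataset_of(len(ddgs))
    for rec, ddg in zip(ds.records, ddgs):
        object.__setattr__(rec, "ddg", float(ddg))
    out = reverse_augment(ds)
    n = len(ds)
    for i in range(n):
        assert -out.records[n + i].ddg == out.records[i].ddg


@given(st.lists(st.floats(-5, 5, allow_nan=False, width=32), min_size=2, max_size=60))
def test_augmented_sign_counts_match_counting_oracle(ddgs):
    """Augmented sign counts against an independent brute-force count."""
    ds = _dataset_of(len(ddgs))
    for rec, ddg in zip(ds.records, ddgs):
        object.__setattr__(rec, "ddg", float(ddg))
    stats = compute_stats(reverse_augment(ds))
    all_vals = [float(d) for d in ddgs] + [-float(d) for d in ddgs]
    assert stats.n_ddg_neg == sum(1 for v in all_vals if v < 0)
    assert stats.n_ddg_nonneg == sum(1 for v in all_vals if v >= 0)
    assert stats.n_ddg_neg + stats.n_ddg_nonneg == stats.n_mutations


# -- splitting ---------------------------------------------------------------

def test_random_split_394_gives_315_79():
    ds = _dataset_of(394)
    train, test = random_split(ds, SplitSpec(train_fraction=0.8, seed=1,
                                             pair_grouping=False))
    assert (len(train), len(test)) == (315, 79)


def test_random_split_degenerate_fraction():
    ds = _dataset_of(10)
    train, test = random_split(ds, SplitSpec(train_fraction=1.0, seed=0))
    assert len(train) == 10 and len(test) == 0


def test_random_split_rejects_bad_fraction():
    with pytest.raises(ValueError):
        SplitSpec(train_fraction=0.0)
    with pytest.raises(ValueError):
        SplitSpec(train_fraction=1.2)


def test_random_split_pair_grouping_keeps_partners_together():
    ds = reverse_augment(_dataset_of(40))
    train, test = random_split(ds, SplitSpec(train_fraction=0.8, seed=3,
                                             pair_grouping=True))
    train_keys = {r.pair_key for r in train.records}
    test_keys = {r.pair_key for r in test.records}
    assert not train_keys & test_keys


@given(st.integers(2, 80), st.floats(0.1, 1.0), st.integers(0, 2**31 - 1))
def test_random_split_partition_laws(n, frac, seed):
    """Partitions are disjoint, exhaustive and seed-deterministic."""
    ds = _dataset_of(n)
    spec = SplitSpec(train_fraction=frac, seed=seed, pair_grouping=False)
    tr1, te1 = random_split(ds, spec)
    tr2, te2 = random_split(ds, spec)
    ids = lambda d: [(r.complex_id, r.position, r.mut_residue) for r in d.records]
    assert ids(tr1) == ids(tr2) and ids(te1) == ids(te2)
    assert len(tr1) == int(np.floor(frac * n))
    assert len(tr1) + len(te1) == n
    assert not set(ids(tr1)) & set(ids(te1))


# -- statistics --------------------------------------------------------------

def test_compute_stats_hand_counts():
    ds = _dataset_of(5)
    for rec, ddg in zip(ds.records, [-1.0, 0.0, 0.5, 1.0, 2.5]):
        object.__setattr__(rec, "ddg", ddg)
    s = compute_stats(ds)
    assert (s.n_ddg_neg, s.n_ddg_nonneg) == (1, 4)
    assert (s.n_ddg_lt1, s.n_ddg_ge1) == (3, 2)
    assert s.n_complexes == 1


def test_compute_stats_empty():
    s = compute_stats(MutationDataset([], {}))
    assert s.n_mutations == 0 and s.n_complexes == 0
    assert s.n_ddg_neg == s.n_ddg_nonneg == s.n_ddg_lt1 == s.n_ddg_ge1 == 0


def test_record_invariants_enforced():
    with pytest.raises(MutationValidationError):
        MutationRecord("1A", "A", "Q", 5, "Q", 1.0)  # identity
    with pytest.raises(MutationValidationError):
        MutationRecord("1A", "A", "B", 5, "A", 1.0)  # non-standard residue
    with pytest.raises(MutationValidationError):
        MutationRecord("1A", "A", "Q", 0, "E", 1.0)  # position < 1
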