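"""Synthetic generator: determinism, planted overlap, emulation envelopes."""

import dataclasses
import io

import pytest

from mrharmony import (
    DataError,
    RegionConfig,
    SyntheticConfig,
    canonicalize_code,
    compare_trees,
    config_from_yaml,
    default_rules,
    generate_code_vocabulary,
    generate_exam_log,
    generate_trees,
    label_statistics,
    run_dx_overlap,
    standardize_tree,
    write_exam_log,
    write_protocol_trees,
)
from mrharmony.synthetic import study_scale, toy


def small_config(seed=0, **overrides):
    region = RegionConfig(
        n_protocols=6,
        n_exams=120,
        code_vocabulary_size=30,
        cardinality_distribution={1: 0.9, 2: 0.1},
        protocol_frequency_range=(6, 40),
        planted_overlaps=(("PA", "PB", 0.5), ("PC", "PD", 0.25)),
    )
    base = dict(
        regions={"spine": region},
        seed=seed,
        n_core_parameter_tuples=24,
        protocols_per_scanner=10,
        synonym_noise_rate=0.3,
        site_specific_sequence_rate=0.2,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestCodeVocabulary:
    def test_codes_are_distinct_and_canonical(self):
        vocab = generate_code_vocabulary(127, seed=3)
        assert len(vocab) == len(set(vocab)) == 127
        assert all(canonicalize_code(c) == c for c in vocab)

    def test_deterministic_under_seed(self):
        assert generate_code_vocabulary(40, seed=5) == generate_code_vocabulary(40, seed=5)

    def test_small_size(self):
        assert len(generate_code_vocabulary(5, seed=1)) == 5


class TestExamLog:
    def test_full_determinism_byte_identical(self, tmp_path):
        for tag in ("a", "b"):
            write_exam_log(generate_exam_log(small_config(seed=11)),
                           tmp_path / f"{tag}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_trees_determinism_byte_identical(self, tmp_path):
        for tag in ("a", "b"):
            write_protocol_trees(generate_trees(small_config(seed=11)),
                                 tmp_path / f"{tag}.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_planted_overlap_recovered_exactly(self):
        records, meta = generate_exam_log(small_config(seed=2), with_meta=True)
        result = run_dx_overlap(records, "spine", min_count=1)
        labels = list(result.matrix.labels)
        for placement in meta["regions"]["spine"]["planted"]:
            i = labels.index(placement.protocol_hi)
            j = labels.index(placement.protocol_lo)
            assert result.matrix.values[i, j] == placement.realized
            assert placement.realized == placement.target

    def test_planted_zero_and_one(self):
        region = RegionConfig(
            n_protocols=8,
            n_exams=150,
            code_vocabulary_size=40,
            cardinality_distribution={1: 1.0},
            protocol_frequency_range=(6, 50),
            planted_overlaps=(("PA", "PB", 0.0), ("PC", "PD", 1.0)),
        )
        config = small_config(regions={"spine": region})
        records, meta = generate_exam_log(config, with_meta=True)
        result = run_dx_overlap(records, "spine", min_count=1)
        labels = list(result.matrix.labels)
        by_pair = {
            (p.protocol_hi, p.protocol_lo): p
            for p in meta["regions"]["spine"]["planted"]
        }
        assert result.matrix.values[labels.index("PA"), labels.index("PB")] == 0.0
        assert result.matrix.values[labels.index("PC"), labels.index("PD")] == 1.0
        assert by_pair[("PA", "PB")].realized == 0.0

    def test_infeasible_planted_overlap_rejected_with_pair(self):
        region = RegionConfig(
            n_protocols=6,
            n_exams=60,
            code_vocabulary_size=30,
            cardinality_distribution={1: 1.0},
            protocol_frequency_range=(6, 20),
            planted_overlaps=(("PA", "PB", 0.123),),  # denominator 1000 > 20
        )
        with pytest.raises(DataError, match="PA"):
            generate_exam_log(small_config(regions={"spine": region}))

    def test_protocol_in_two_pairs_rejected(self):
        with pytest.raises(DataError, match="at most one planted pair"):
            RegionConfig(
                n_protocols=8,
                n_exams=100,
                code_vocabulary_size=30,
                cardinality_distribution={1: 1.0},
                protocol_frequency_range=(6, 40),
                planted_overlaps=(("PA", "PB", 0.5), ("PB", "PC", 0.5)),
            )

    def test_cardinality_envelope(self):
        # binomial mean 1.1, 1000 exams -> realized mean within 3 sigma
        region = RegionConfig(
            n_protocols=10,
            n_exams=1000,
            code_vocabulary_size=60,
            cardinality_distribution={1: 0.9, 2: 0.1},
            protocol_frequency_range=(6, 400),
        )
        records = generate_exam_log(small_config(regions={"spine": region}))
        stats = label_statistics(records)
        assert 1.05 <= stats.cardinality <= 1.15

    def test_frequencies_respect_range_and_total(self):
        records, meta = generate_exam_log(small_config(seed=9), with_meta=True)
        counts = meta["regions"]["spine"]["protocol_counts"]
        assert sum(counts.values()) == 120 == len(records)
        assert all(6 <= c <= 40 for c in counts.values())


class TestTrees:
    def test_no_noise_no_site_effects_identical_name_sets(self):
        config = small_config(
            synonym_noise_rate=0.0, site_specific_sequence_rate=0.0
        )
        report = compare_trees(generate_trees(config), "scanner1", default_rules())
        for sid, entry in report.scanners.items():
            if entry.oc_vs_reference is not None:
                assert entry.oc_vs_reference["raw"] == 1.0
                assert entry.oc_vs_reference["protocol"] == 1.0

    def test_shared_core_with_noise_standardized_exceeds_raw(self):
        config = small_config(
            synonym_noise_rate=0.5, site_specific_sequence_rate=0.0
        )
        report = compare_trees(generate_trees(config), "scanner1", default_rules())
        for entry in report.scanners.values():
            if entry.oc_vs_reference is not None:
                assert entry.oc_vs_reference["standardized"] == 1.0
                assert entry.oc_vs_reference["raw"] < 1.0

    def test_standardized_count_strictly_below_raw(self):
        for seed in (0, 1, 2):
            for tree in generate_trees(small_config(seed=seed)):
                _, summary = standardize_tree(tree, default_rules())
                assert summary.n_unique_standardized < summary.n_unique_raw

    def test_scanner_ids_and_sites(self):
        trees = generate_trees(small_config())
        assert [t.scanner_id for t in trees] == ["scanner1", "scanner2", "scanner3"]
        assert [t.site_id for t in trees] == ["siteA", "siteA", "siteB"]


class TestConfigs:
    def test_study_scale_loads_from_yaml_equivalently(self, tmp_path):
        import pathlib

        repo = pathlib.Path(__file__).resolve().parent.parent
        config = config_from_yaml(repo / "configs" / "study_scale.yaml")
        assert config == study_scale()

    def test_toy_yaml_runs_end_to_end(self):
        import pathlib

        repo = pathlib.Path(__file__).resolve().parent.parent
        config = config_from_yaml(repo / "configs" / "toy.yaml", seed=4)
        records = generate_exam_log(config)
        assert len(records) == 60
        trees = generate_trees(config)
        assert len(trees) == 3

    def test_seed_override(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text(
            "seed: 1\nregions:\n  spine:\n    n_protocols: 2\n    n_exams: 20\n"
            "    code_vocabulary_size: 10\n    cardinality_distribution: {1: 1.0}\n"
            "    protocol_frequency_range: [5, 15]\n",
            encoding="utf-8",
        )
        assert config_from_yaml(path, seed=7).seed == 7
        assert config_from_yaml(path).seed == 1
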