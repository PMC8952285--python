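import numpy as np
import pandas as pd
import pytest

from capcri.diagnosis import (SUMMARY_NAMES, SubjectDiagnoser, SubjectSummary,
                              TrainingLibrary, summarize_subject)
from capcri.features import FEATURE_NAMES
from capcri.staging import CHARACTERISTIC_NAMES


def _frame(rng, n=120, cra_level=3.0, labels=None):
    df = pd.DataFrame(rng.standard_normal((n, len(CHARACTERISTIC_NAMES))),
                      columns=CHARACTERISTIC_NAMES)
    df["cra"] = cra_level + 0.3 * rng.standard_normal(n)
    if labels is None:
        labels = (["W"] * 20 + ["S2-NA"] * 40 + ["S3-NA"] * 30
                  + ["S4-NA"] * 20 + ["R"] * 10)[:n]
    return df, labels


class TestSummarizeSubject:
    def test_deterministic(self, rng):
        df, labels = _frame(rng)
        a = summarize_subject(df, labels, "s")
        b = summarize_subject(df, labels, "s")
        np.testing.assert_array_equal(a.values, b.values)

    def test_invariant_to_epoch_order_within_stages(self, rng):
        df, labels = _frame(rng)
        perm = rng.permutation(len(df))
        df2 = df.iloc[perm].reset_index(drop=True)
        labels2 = [labels[i] for i in perm]
        a = summarize_subject(df, labels, "s")
        b = summarize_subject(df2, labels2, "s")
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

    def test_no_deep_sleep_block_missing_no_crash(self, rng):
        df, _ = _frame(rng, n=60)
        labels = ["W"] * 30 + ["S2-NA"] * 30
        s = summarize_subject(df, labels, "s")
        series = s.as_series()
        assert np.isnan(series["deep.cra"])
        assert np.isfinite(series["S2.cra.mean"])

    def test_too_few_epochs_rejected(self, rng):
        df, labels = _frame(rng, n=5)
        with pytest.raises(ValueError):
            summarize_subject(df, labels[:5], "s")

    def test_summary_length_matches_names(self, rng):
        df, labels = _frame(rng)
        s = summarize_subject(df, labels, "s")
        assert s.values.size == len(SUMMARY_NAMES)


class TestSubjectDiagnoser:
    @pytest.fixture
    def cohort_summaries(self, rng):
        """Synthetic summaries with group-wide feature signatures, the way
        the coupling profiles shift every CRI/HRV feature at once."""
        signatures = {g: 2.0 * rng.standard_normal(len(CHARACTERISTIC_NAMES))
                      for g in ("healthy", "insomnia", "narcolepsy")}
        out, groups = [], []
        for g, sig in signatures.items():
            for k in range(6):
                df, labels = _frame(rng)
                df[CHARACTERISTIC_NAMES] = (df[CHARACTERISTIC_NAMES]
                                            + sig[None, :])
                out.append(summarize_subject(df, labels, f"{g}{k}"))
                groups.append(g)
        return out, groups

    def test_leave_one_out_recovers_groups(self, cohort_summaries):
        from sklearn.metrics import balanced_accuracy_score
        summaries, groups = cohort_summaries
        preds = []
        for i in range(len(summaries)):
            train = [s for j, s in enumerate(summaries) if j != i]
            gtr = [g for j, g in enumerate(groups) if j != i]
            d = SubjectDiagnoser(random_state=0).fit(train, gtr)
            preds.append(d.predict([summaries[i]])[0])
        assert balanced_accuracy_score(groups, preds) >= 0.85

    def test_training_centroid_assigned_to_its_group(self, cohort_summaries):
        summaries, groups = cohort_summaries
        d = SubjectDiagnoser(random_state=0).fit(summaries, groups)
        assert d.predict([summaries[0]])[0] == groups[0]

    def test_single_class_training_rejected(self, cohort_summaries):
        summaries, _ = cohort_summaries
        with pytest.raises(ValueError):
            SubjectDiagnoser().fit(summaries[:4], ["healthy"] * 4)

    def test_diagnose_returns_margins(self, cohort_summaries):
        summaries, groups = cohort_summaries
        d = SubjectDiagnoser(random_state=0).fit(summaries, groups)
        out = d.diagnose(summaries[0])
        assert out["group"] in ("healthy", "insomnia", "narcolepsy")
        assert set(out["margins"]) == {"healthy", "insomnia", "narcolepsy"}

    def test_monotone_margin_in_contrast(self, rng):
        """A larger simulated insomnia A/NA CRA swing raises the mean
        insomnia margin of probe subjects."""

        def cohort(contrast):
            out, groups = [], []
            specs = [("healthy", 3.5, -0.5), ("insomnia", 5.0, contrast),
                     ("narcolepsy", 1.2, -0.2)]
            for g, level, swing in specs:
                for k in range(5):
                    labels = (["S3-NA"] * 50 + ["S3-A2"] * 20
                              + ["S4-NA"] * 30 + ["W"] * 20)
                    df, _ = _frame(rng, n=120, cra_level=level)
                    a_rows = [i for i, l in enumerate(labels)
                              if l.endswith("A2")]
                    df.loc[a_rows, "cra"] = level + swing \
                        + 0.3 * rng.standard_normal(len(a_rows))
                    out.append(summarize_subject(df, labels, f"{g}{k}"))
                    groups.append(g)
            return out, groups

        train, groups = cohort(contrast=-3.0)
        d = SubjectDiagnoser(random_state=0).fit(train, groups)
        idx = list(d.classes_).index("insomnia")

        def mean_margin(contrast):
            probes, pg = cohort(contrast)
            probes = [s for s, g in zip(probes, pg) if g == "insomnia"]
            return float(np.mean(d.decision_function(probes)[:, idx]))

        assert mean_margin(-3.0) > mean_margin(-0.5)


class TestTrainingLibrary:
    def _summary(self, rng, sid):
        df, labels = _frame(rng)
        return summarize_subject(df, labels, sid)

    def test_append_grows_training_set(self, rng):
        lib = TrainingLibrary()
        for g, sid in [("healthy", "a"), ("healthy", "b"), ("healthy", "c"),
                       ("insomnia", "d"), ("insomnia", "e"),
                       ("narcolepsy", "f")]:
            lib.update(self._summary(rng, sid), g)
        n = len(lib)
        lib.update(self._summary(rng, "g"), "insomnia")
        assert len(lib) == n + 1
        assert lib.version == n + 1

    def test_duplicate_subject_rejected(self, rng):
        lib = TrainingLibrary()
        lib.update(self._summary(rng, "x"), "healthy")
        with pytest.raises(ValueError, match="duplicate"):
            lib.update(self._summary(rng, "x"), "healthy")

    def test_dimension_mismatch_rejected(self, rng):
        lib = TrainingLibrary()
        lib.update(self._summary(rng, "x"), "healthy")
        bad = SubjectSummary(np.zeros(3), "y")
        with pytest.raises(ValueError, match="dimension"):
            lib.update(bad, "insomnia")

    def test_roundtrip_through_disk(self, rng, tmp_path):
        lib = TrainingLibrary()
        lib.update(self._summary(rng, "x"), "healthy")
        lib.update(self._summary(rng, "y"), "narcolepsy")
        path = tmp_path / "library.json"
        lib.to_json(path)
        back = TrainingLibrary.from_json(path)
        assert back.version == lib.version
        assert back.groups == lib.groups
        for a, b in zip(lib.summaries, back.summaries):
            np.testing.assert_allclose(a.values, b.values, equal_nan=True)
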