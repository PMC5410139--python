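#!/usr/bin/env python
"""Body-size statistics of the two new mole-rat species.

Validates the packaged collection table, then computes the adult body-weight
summaries and the male-vs-female pooled t test for the Hanang/Mbulu species.
Writes results/specimen_statistics.json.
"""

import json
from pathlib import Path

from fukomys.pipeline import validate_fixture_tables
from fukomys.specimens import (
    adult_mask,
    dimorphism_t_test,
    group_summary,
    load_specimen_table,
    sex_mask,
)

OUT = Path("results")
OUT.mkdir(exist_ok=True)


def main() -> None:
    report = validate_fixture_tables()
    assert report["passed"], report
    print("fixture table: all integrity checks passed "
          f"({len(report['checks'])} checks)")

    df = load_specimen_table()
    out = {}
    for label, species, rule in [
        ("hanangensis_adult", "F. hanangensis", "exclude_class1"),
        ("livingstoni_adult", "F. livingstoni", "class2_plus"),
        ("whytei_all", "F. whytei", "exclude_class1"),
    ]:
        s = group_summary(df, adult_mask(df, species, rule))
        out[label] = {
            "n": s.n, "mean_g": round(s.mean, 2),
            "sem_g": None if s.sem is None else round(s.sem, 2),
            "range_g": [s.minimum, s.maximum],
        }
        print(f"{species:16s} adults: n={s.n:2d} "
              f"mean={s.mean:6.1f} g  SEM={s.sem:.1f}  "
              f"range {s.minimum:.0f}-{s.maximum:.0f} g")

    adults = adult_mask(df, "F. hanangensis", "exclude_class1")
    for sex in ("male", "female"):
        s = group_summary(df, adults & sex_mask(df, sex))
        out[f"hanangensis_{sex}"] = {"n": s.n, "mean_g": round(s.mean, 2),
                                     "sem_g": round(s.sem, 2)}
        print(f"hanangensis {sex:6s}: n={s.n} mean={s.mean:.1f} g")

    t = dimorphism_t_test(df)
    out["dimorphism_t_test"] = {
        "t": round(t.value, 3), "df": t.df[0], "p": round(t.p_value, 3),
    }
    print(f"sex difference: t={t.value:.3f}, df={t.df[0]}, p={t.p_value:.3f} "
          "-> males heavier but not significantly so")

    (OUT / "specimen_statistics.json").write_text(json.dumps(out, indent=2))
    print("written: results/specimen_statistics.json")


if __name__ == "__main__":
    main()
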