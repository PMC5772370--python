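"""Simulated extrusion series: size, Span and count per passage.

Starts from a broad lognormal vesicle population and pushes it repeatedly
through a 100 nm pore (partial per-passage fragmentation, so break-up is
spread over several passages as in a real extruder).  Tracks the
number-weighted mean, Span, PDI and particle count after each passage —
the homogenization trajectory an extrusion experiment records.  Writes
results/extrusion_series.csv.
"""

from pathlib import Path

import pandas as pd

from colloidstat.dispersity import classify_dispersity, summarize
from colloidstat.synthetic import extrude, make_population

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main():
    RESULTS.mkdir(exist_ok=True)
    start = make_population(3000, [(400.0, 1.6, 1.0)], seed=SEED)
    rows = []
    for k in range(7):
        pop = extrude(start, 100.0, k, seed=SEED + 1, efficiency=0.7)
        s = summarize(pop.diameters)
        rows.append(
            {
                "passages": k,
                "n_particles": pop.n_particles,
                "mean_nm": s.mean_number_weighted,
                "z_average_nm": s.z_average,
                "pdi": s.pdi,
                "span": s.span,
                "dispersity": classify_dispersity(s.pdi, s.span),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "extrusion_series.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print(
        "\nRepeated passages homogenize the population: mean size and Span "
        "fall monotonically while the particle count rises — small vesicles "
        "multiply out of large ones, membrane area conserved."
    )


if __name__ == "__main__":
    main()
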