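"""Job-plot stoichiometry of the simulated continuous-variation series."""

from pathlib import Path

import pandas as pd

from hsabind import io as hio
from hsabind.jobplot import find_job_maximum, stoichiometry_from_chi

ROOT = Path(__file__).resolve().parent.parent
DATA, OUT = ROOT / "results" / "data", ROOT / "results"


def main() -> None:
    rows = []
    for path in sorted(DATA.glob("job_*.csv")):
        series = hio.read_job_csv(path)
        chi_max, s_max = find_job_maximum(series)
        call = stoichiometry_from_chi(chi_max)
        ratio = (
            f"{call.n_ratio.numerator}:{call.n_ratio.denominator}"
            if call.snapped
            else "unsnapped"
        )
        rows.append(
            {
                "series": series.label or path.stem,
                "chi_max_protein": round(chi_max, 3),
                "signal_max": round(s_max, 4),
                "n_ligand_per_protein": round(call.n_continuous, 3),
                "stoichiometry_ligand_protein": ratio,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "table_job.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
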