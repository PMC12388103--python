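"""UV and emission lambda-max shifts of drug-bound vs protein-only spectra.

A positive (bathochromic) shift signals increased polarity around the
aromatic residues; negative (hypsochromic) increased hydrophobicity.
"""

from pathlib import Path

import pandas as pd

from hsabind import io as hio
from hsabind.spectra import find_lambda_max, peak_shift

ROOT = Path(__file__).resolve().parent.parent
DATA, OUT = ROOT / "results" / "data", ROOT / "results"

UV_WINDOW = (200.0, 240.0)  # backbone absorption band


def main() -> None:
    rows = []
    ref_uv = hio.read_spectrum_csv(DATA / "uv_reference.csv", kind="absorption")
    ref_em = hio.read_spectrum_csv(DATA / "emission_reference.csv", kind="emission")
    for kind, ref, window in [
        ("uv", ref_uv, UV_WINDOW),
        ("emission", ref_em, None),
    ]:
        for path in sorted(DATA.glob(f"{kind}_*.csv")):
            if path.name.endswith("reference.csv"):
                continue
            spec = hio.read_spectrum_csv(
                path, kind="absorption" if kind == "uv" else "emission"
            )
            lam_ref, _ = find_lambda_max(ref, window, interpolate=True)
            lam_test, _ = find_lambda_max(spec, window, interpolate=True)
            delta, cls = peak_shift(ref, spec, window)
            rows.append(
                {
                    "band": kind,
                    "system": spec.label or path.stem,
                    "lambda_ref_nm": round(lam_ref, 1),
                    "lambda_test_nm": round(lam_test, 1),
                    "delta_nm": round(delta, 1),
                    "classification": cls,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "table_shifts.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
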