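"""Deterministic plain-text report assembly.

Mirrors the layouts of the standard spectroscopic result tables: UV λmax
shifts, Stern-Volmer fits with mechanism calls, double-log binding fits with
ΔG, EEM peak reductions, and the Job-plot stoichiometry. Identical inputs
produce byte-identical output; run metadata (seed, config) is segregated in
the header so numeric tables stay timestamp-free.
"""

from __future__ import annotations

from .datamodel import BindingFit, MechanismCall, QuenchFit, ReductionRow, StoichiometryCall

__all__ = ["build_report"]


def _table(headers: list[str], rows: list[list[str]]) -> str:
    widths = [
        max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
        for i, h in enumerate(headers)
    ]
    def fmt(cells):
        return "  ".join(c.ljust(w) for c, w in zip(cells, widths)).rstrip()
    lines = [fmt(headers), fmt(["-" * w for w in widths])]
    lines += [fmt(r) for r in rows]
    return "\n".join(lines)


def build_report(bundle: dict, run_metadata: dict | None = None) -> str:
    """Assemble a plain-text report from a results bundle.

    Recognised bundle keys (all optional, at least one required):

    - ``uv_shifts``: list of dicts with label, lambda_ref, lambda_test,
      delta, classification
    - ``sv_fits``: list of (QuenchFit, MechanismCall | None)
    - ``binding_fits``: list of BindingFit
    - ``eem_reductions``: list of ReductionRow
    - ``job``: (chi_max, signal_max, StoichiometryCall)
    """
    if not bundle:
        raise ValueError("empty results bundle")
    sections: list[str] = ["# Spectroscopic binding analysis report"]
    if run_metadata:
        sections.append(
            "\n".join(f"{k}: {run_metadata[k]}" for k in sorted(run_metadata))
        )

    if "uv_shifts" in bundle:
        rows = [
            [
                d["label"],
                f"{d['lambda_ref']:.1f}",
                f"{d['lambda_test']:.1f}",
                f"{d['delta']:+.1f}",
                d["classification"],
            ]
            for d in bundle["uv_shifts"]
        ]
        sections.append(
            "## UV absorption peak shifts\n"
            + _table(
                ["System", "Ref λmax (nm)", "Test λmax (nm)", "Δλ (nm)", "Class"],
                rows,
            )
        )

    if "sv_fits" in bundle:
        rows = []
        for fit, call in bundle["sv_fits"]:
            assert isinstance(fit, QuenchFit)
            rows.append(
                [
                    fit.label or "-",
                    f"{fit.ksv / 1e3:.2f} ± {fit.ksv_se / 1e3:.2f}",
                    f"{fit.kq / 1e11:.2f}",
                    f"{fit.r_squared:.2f}",
                    f"{fit.intercept:.2f} ± {fit.intercept_se:.2f}",
                    f"{fit.ksv:.2f}",
                    call.label if isinstance(call, MechanismCall) else "-",
                ]
            )
        sections.append(
            "## Stern-Volmer analysis\n"
            + _table(
                [
                    "Ligand",
                    "K_sv (10^3 L/mol)",
                    "K_q (10^11 L/mol/s)",
                    "R^2",
                    "Intercept",
                    "Slope",
                    "Mechanism",
                ],
                rows,
            )
        )

    if "binding_fits" in bundle:
        rows = []
        for fit in bundle["binding_fits"]:
            assert isinstance(fit, BindingFit)
            rows.append(
                [
                    fit.label or "-",
                    f"{fit.log_kb:.2f}",
                    f"{fit.kb / 1e3:.2f}",
                    f"{fit.n_sites:.2f}",
                    f"{fit.r_squared:.2f}",
                    f"{fit.delta_g:.1f}",
                    str(len(fit.excluded_points)),
                ]
            )
        sections.append(
            "## Binding constants and free energy\n"
            + _table(
                [
                    "Ligand",
                    "logK_b",
                    "K_b (10^3 L/mol)",
                    "n",
                    "R^2",
                    "ΔG (kJ/mol)",
                    "Excluded",
                ],
                rows,
            )
        )

    if "eem_reductions" in bundle:
        rows = []
        for r in bundle["eem_reductions"]:
            assert isinstance(r, ReductionRow)
            rows.append(
                [
                    r.system_label,
                    f"{r.molar_ratio:g}:1",
                    str(r.peak_id),
                    f"{r.intensity_test:.0f}",
                    f"{r.reduction_percent}%" if r.valid else "invalid",
                    f"{r.em_shift:+.1f}",
                ]
            )
        sections.append(
            "## Three-dimensional fluorescence peak reductions\n"
            + _table(
                [
                    "System",
                    "Drug/HSA",
                    "Peak",
                    "Intensity",
                    "Reduction Percent",
                    "Em shift (nm)",
                ],
                rows,
            )
        )

    if "job" in bundle:
        chi_max, signal_max, call = bundle["job"]
        assert isinstance(call, StoichiometryCall)
        ratio = (
            f"{call.n_ratio.numerator}:{call.n_ratio.denominator} (ligand:protein)"
            if call.snapped and call.n_ratio is not None
            else f"unsnapped, n = {call.n_continuous:.3f}"
        )
        sections.append(
            "## Job-plot stoichiometry\n"
            f"chi_max (protein mole fraction): {chi_max:.3f}\n"
            f"signal at maximum: {signal_max:.6g}\n"
            f"stoichiometry: {ratio}"
        )

    if len(sections) == 1 + (1 if run_metadata else 0):
        raise ValueError("results bundle contains no recognised sections")
    return "\n\n".join(sections) + "\n"
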