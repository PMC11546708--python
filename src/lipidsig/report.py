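"""Human-readable markdown summary of a pipeline run directory."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

SECTIONS = (
    "Simulation",
    "QC reproducibility",
    "Differential-abundance panel",
    "ML discovery",
    "Final ensemble",
    "Sensitivity analysis",
    "Panel comparison",
)


def _missing(name: str) -> list[str]:
    return [f"## {name}", "", "_missing stage: artifacts not found_", ""]


def render_report(out_dir: str | Path, signature_size: int = 20) -> str:
    """Assemble a markdown report from whatever stage artifacts exist."""
    out = Path(out_dir)
    lines = ["# lipidsig run report", ""]

    # Simulation
    truth_p = out / "truth.json"
    if truth_p.exists():
        truth = json.loads(truth_p.read_text())
        lines += [
            "## Simulation",
            "",
            f"- planted informative lipids: {len(truth['informative_lipids'])}",
            f"- informative set: {', '.join(truth['informative_lipids'])}",
            "",
        ]
    else:
        lines += _missing("Simulation")

    # QC
    qc_p = out / "qc_report.csv"
    if qc_p.exists():
        qc = pd.read_csv(qc_p)
        lines += ["## QC reproducibility", ""]
        for stype, sub in qc.groupby("sample_type"):
            lines.append(
                f"- {stype}: median CV {sub['cv_percent'].median():.1f}%, "
                f"{int(sub['flag_30'].sum())} of {len(sub)} lipids with CV >= 30%"
            )
        lines.append("")
    else:
        lines += _missing("QC reproducibility")

    # DA panel
    loocv_p = out / "loocv.json"
    panel_p = out / "da_panel.csv"
    if loocv_p.exists() and panel_p.exists():
        res = json.loads(loocv_p.read_text())
        panel = pd.read_csv(panel_p)
        c = res["confusion"]
        lines += [
            "## Differential-abundance panel",
            "",
            f"- panel size: {len(panel)} lipids",
            f"- LOOCV accuracy {res['accuracy']:.3f}, sensitivity {res['sensitivity']:.3f}, "
            f"specificity {res['specificity']:.3f}, AUC {res['auc']:.3f} "
            f"(threshold {res['threshold']:.3f})",
            "",
            "| index test \\ reference | cancer | control |",
            "|---|---|---|",
            f"| pred_cancer | {c['tp']} | {c['fp']} |",
            f"| pred_control | {c['fn']} | {c['tn']} |",
            "",
        ]
    else:
        lines += _missing("Differential-abundance panel")

    # ML discovery
    freq_p = out / "selection_frequency.csv"
    if freq_p.exists():
        freq = pd.read_csv(freq_p, index_col=0).head(30)
        lines += [
            "## ML discovery",
            "",
            f"Top 30 lipids by Boruta selection frequency "
            f"(cutoff marked after the top {signature_size}):",
            "",
            "| rank | lipid | proportion |",
            "|---|---|---|",
        ]
        for i, (lid, row) in enumerate(freq.iterrows(), start=1):
            mark = " <- signature cutoff" if i == signature_size else ""
            lines.append(f"| {i} | {lid} | {row['proportion']:.3f}{mark} |")
        lines.append("")
    else:
        lines += _missing("ML discovery")

    # Final ensemble
    fin_p = out / "final_summary.json"
    if fin_p.exists():
        s = json.loads(fin_p.read_text())
        lines += [
            "## Final ensemble",
            "",
            f"- accuracy {100 * s['accuracy_mean']:.1f} +/- {100 * s['accuracy_sd']:.1f}%",
            f"- sensitivity {100 * s['sensitivity_mean']:.1f} +/- {100 * s['sensitivity_sd']:.1f}%",
            f"- specificity {100 * s['specificity_mean']:.1f} +/- {100 * s['specificity_sd']:.1f}%",
            f"- mean AUC {s['auc_mean']:.3f}",
            "",
            "Certainty of predictions (percent within outcome class):",
            "",
        ]
        for key, v in sorted(s.get("certainty_percent", {}).items()):
            lines.append(f"- {key}: {v:.1f}%")
        lines.append("")
    else:
        lines += _missing("Final ensemble")

    # Sensitivity
    sens_p = out / "sensitivity.csv"
    if sens_p.exists():
        sens = pd.read_csv(sens_p, index_col=0)
        chosen = None
        if fin_p.exists():
            chosen = json.loads(fin_p.read_text()).get("chosen_signature_size")
        lines += ["## Sensitivity analysis", ""]
        lines += ["| size | q05 | median | q95 |", "|---|---|---|---|"]
        for k, row in sens.iterrows():
            star = " *" if chosen is not None and int(k) == int(chosen) else ""
            lines.append(
                f"| {k}{star} | {row['q05']:.3f} | {row['median']:.3f} | {row['q95']:.3f} |"
            )
        lines.append("")
    else:
        lines += _missing("Sensitivity analysis")

    # Panels
    overlap_p = out / "overlap.csv"
    if overlap_p.exists():
        ov = pd.read_csv(overlap_p)
        lines += ["## Panel comparison", ""]
        lines += ["| region | n | lipids |", "|---|---|---|"]
        for _, row in ov.iterrows():
            lip = row["lipids"] if isinstance(row["lipids"], str) else ""
            lines.append(f"| {row['region']} | {row['n_lipids']} | {lip} |")
        lines.append("")
    else:
        lines += _missing("Panel comparison")

    return "\n".join(lines)
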