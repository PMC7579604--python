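"""Leave-one-feature-out importance of the fixed-field ANN.

Under a design where nature-of-injury dominates the outcome, retrains the
ANN once per original variable (all derived columns of a categorical
removed together) and ranks features by the drop in held-out weighted F1.
"""

from pathlib import Path

from mineinjury.studies import importance_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    table = importance_study(n=3000, seed=0)
    frame = table.to_frame().round(4)
    out = ROOT / "results" / "feature_importance.csv"
    out.parent.mkdir(exist_ok=True)
    frame.to_csv(out, index=False)
    print(f"baseline weighted F1: {table.baseline_f1:.3f}")
    print(frame.to_string(index=False))
    top, delta = table.entries[0]
    print(f"\nfinding: {top} ranks first (delta F1 {delta:.3f}); null features sit near zero.")


if __name__ == "__main__":
    main()
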