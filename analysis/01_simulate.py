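"""Draw the study-scale synthetic exit-interview survey.

1400 patients at up to 10 per facility across 150 facilities, with
wealth-dependent travel-mode choice, zero-inflated direct costs, and
time costs declining in wealth rank.  Writes the canonical survey CSV
plus the ground-truth sidecars under results/synthetic/.
"""

from pathlib import Path

from equicost.survey_data import write_canonical
from equicost.synthetic import default_config, generate_survey

SEED = 2025

if __name__ == "__main__":
    out = Path("results/synthetic")
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth, params = generate_survey(default_config(SEED),
                                             return_truth=True)
    write_canonical(dataset, out / "survey.csv")
    truth.to_csv(out / "truth.csv", index=False)
    params.to_csv(out / "outcome_params.csv", index=False)

    df = dataset.df
    print(f"simulated {len(df)} patients at {df.facility_id.nunique()} facilities")
    print(f"  on foot: {(df.travel_mode == 'foot').mean():.1%}   "
          f"public: {(df.ownership == 'public').mean():.1%}   "
          f"rural: {(df.residence == 'rural').mean():.1%}")
    print(f"  paying for care: {(df.medical_cost_tzs.dropna() > 0).mean():.1%}   "
          f"paying for transport: {(df.transport_cost_tzs.dropna() > 0).mean():.1%}")
    print(f"wrote survey.csv, truth.csv, outcome_params.csv to {out}/")
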