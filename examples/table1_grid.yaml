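# Canonical sensitivity grid: three conventional-pathway blocks (fixed
# tPA/ECR components 95/125, 85/115, 75/105 min) with CT-perfusion and
# telemedicine add-ons. Same grid as msureach.table1_grid().
- {msu: {}, usual: {}}
- {msu: {ctp_min: 10.0}, usual: {}}
- {msu: {tele_min: 10.0}, usual: {}}
- {msu: {ctp_min: 10.0, tele_min: 10.0}, usual: {}}
- {msu: {tele_min: 20.0}, usual: {}}
- {msu: {tele_min: 30.0}, usual: {}}
- {msu: {}, usual: {door_to_needle_min: 50.0, door_to_groin_min: 80.0}}
- {msu: {tele_min: 10.0}, usual: {door_to_needle_min: 50.0, door_to_groin_min: 80.0}}
- {msu: {tele_min: 20.0}, usual: {door_to_needle_min: 50.0, door_to_groin_min: 80.0}}
- {msu: {}, usual: {door_to_needle_min: 40.0, door_to_groin_min: 70.0}}
- {msu: {tele_min: 10.0}, usual: {door_to_needle_min: 40.0, door_to_groin_min: 70.0}}
- {msu: {tele_min: 20.0}, usual: {door_to_needle_min: 40.0, door_to_groin_min: 70.0}}
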