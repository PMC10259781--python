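# Full pipeline configuration example (all keys optional; defaults shown).
# Run:  pvonset all --config examples/pipeline_config.yaml --tables dump/

tables_dir: "."
table_files:
  DEMO: DEMO.csv
  DRUG: DRUG.csv
  REAC: REAC.csv
  HIST: HIST.csv
# Map schema fields to the file's column headers per table, e.g. for a raw
# Japanese-header dump:
# column_mapping:
#   DEMO: {case_id: "識別番号", sex: "性別", age: "年齢"}
delimiter: ","
encoding: "utf-8"        # real dumps: cp932

term_list: null          # null -> bundled demo convulsions list
drug_name: "clozapine"
antipsychotic_list: null # null -> bundled list
antiepileptic_list: null

dose_low_edge: 200.0     # mg/day; < edge -> low
dose_high_edge: 400.0    # > edge -> high; [low, high] -> medium
lithium_edge: 600.0      # <= edge -> low, > edge -> high
dose_rule: "max"         # max | first | mean over a case's study-drug rows
sex_reference: "male"

window_days: 1095
day_convention: "plus_one"   # plus_one | half_day
histogram_bin_days: 30.0

out_dir: "pvonset_out"
seed: 0
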