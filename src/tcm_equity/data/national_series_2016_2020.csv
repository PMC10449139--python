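# National annual totals of the four TCM health-resource indicators, 2016-2020.
# institutions = TCM medical institutions; beds = TCM beds;
# practitioners = practitioners (assistants) of TCM; pharmacists = Chinese pharmacists.
year,institutions,beds,practitioners,pharmacists
2016,49527,1033547,481590,116622
2017,54243,1135525,527047,120302
2018,60738,1234237,575454,123913
2019,65809,1328752,624783,127154
2020,72355,1432900,682770,131163
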