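{
  "asv_table.tsv": "f9cd4129c28d4b906fffd47d9dfcc0415d6367cb9d7177650b8b03040f321e87",
  "metadata.tsv": "5f7247440c923ff85f5c11961c2f1287a41694200c5fb3ff05704a391e4772a0",
  "taxonomy.tsv": "f3be2b0505517e405413b7df138b9b8d9143076cb46d727933e05c143c4c172a",
  "truth.json": "a75464d94e1e8e5fa1c09fadc72c8bb35042a2804856cccf0156f4bc231fd960"
}
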