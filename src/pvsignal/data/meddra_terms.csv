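pt_code,pt_name
10050208,Teratospermia
10030300,Oligospermia
10067162,Asthenospermia
10041493,Spermatogenesis abnormal
10021929,Infertility male
10079294,Oligoasthenoteratozoospermia
10080320,Oligoasthenozoospermia
10074268,Reproductive toxicity
10074729,Necrospermia
10003495,Aspermia
10003883,Azoospermia
10049572,Testicular necrosis
10043298,Testicular atrophy
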