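drug,atc_code
BLEOMYCIN,L01DC01
CARBAMAZEPINE,N03AF01
CHORIONIC GONADOTROPHIN,G03GA01
CITALOPRAM,N06AB04
DOXORUBICIN,L01DB01
DUTASTERIDE,G04CB02
ETOPOSIDE,L01CB01
FINASTERIDE,G04CB01
FINASTERIDE,D11AX10
HYDROXYCARBAMIDE,L01XX05
LEUPRORELIN,L02AE02
MEDROXYPROGESTERONE,G03DA02
MEDROXYPROGESTERONE,L02AB02
MINOXIDIL,C02DC01
MINOXIDIL,D11AX01
PAROXETINE,N06AB05
SULFASALAZINE,A07EC01
TAMSULOSIN,G04CA02
TESTOSTERONE,G03BA03
TRIPTORELIN,L02AE04
VALPROIC ACID,N03AG01
VINBLASTINE,L01CA01
IBUPROFEN,M01AE01
METFORMIN,A10BA02
AMOXICILLIN,J01CA04
ATORVASTATIN,C10AA05
OMEPRAZOLE,A02BC01
SALBUTAMOL,R03AC02
LORATADINE,R06AX13
SERTRALINE,N06AB06
LISINOPRIL,C09AA03
WARFARIN,B01AA03
PREDNISONE,H02AB07
LEVOTHYROXINE,H03AA01
FUROSEMIDE,C03CA01
GABAPENTIN,N03AX12
TRAMADOL,N02AX02
CETIRIZINE,R06AE07
DOXYCYCLINE,J01AA02
INSULIN GLARGINE,A10AE04
TIMOLOL,S01ED01
ACICLOVIR,J05AB01
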