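>TUBA1A
EDMAALEKDYEEVGVDSVEGEGEEEGEEY
>TUBA1B
EDMAALEKDYEEVGVDSVEGEGEEEGEEY
>TUBB5
NDLVSEYQQYQDATAEEEEDFGEEAEEEA
>TUBB4B
NDLVSEYQQYQDATAEEEGEFEEEAEEEVA
>TUBB2A
NDLVSEYQQYQDATADEQGEFEEEEGEDEA
>TUBB2B
NDLVSEYQQYQDATADEQGEFEEEEGEDEA
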