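{
  "labels": {
    "1": "Prokaryotes, protists, and funguses",
    "2": "Plants",
    "3": "Invertebrates",
    "4": "Fishes",
    "5": "Amphibians",
    "6": "Reptiles",
    "7": "Birds",
    "8": "Wild mammals",
    "9": "Domestic mammals and pets",
    "10": "Human"
  },
  "entries": {
    "Euglena": 1, "Bacterium": 1, "Amoeba": 1, "Mushroom": 1, "Algae": 1,
    "Paramecium": 1, "Monera": 1, "Protists": 1, "Plasmodium": 1,
    "Plankton": 1, "Planaria": 1,

    "Daisy": 2, "Plant(s)": 2, "Tree(s)": 2, "Rose": 2, "Flower(s)": 2,
    "Cactus": 2, "Grass": 2, "Fern": 2, "Tulip": 2, "Chrysanthemum": 2,
    "Sunflower": 2, "Hyacinth": 2, "Blackberry": 2, "Lotus": 2,
    "Jasmine": 2, "Mistletoe": 2, "Purslane": 2, "Daffodil": 2, "Kiwi": 2,
    "Snowdrop": 2, "Willow": 2, "Geranium": 2, "Begonia": 2, "Violet": 2,

    "Parasite(s)": 3, "Earthworm": 3, "Spider": 3, "Beetle(s)": 3,
    "Butterfly": 3, "Bee": 3, "Grasshopper": 3, "Scorpion": 3, "Fly": 3,
    "Ant": 3, "Caterpillar": 3, "Cancer": 3, "Millipede": 3,
    "Sea cucumber": 3, "Tick": 3, "Snail": 3, "Hydra": 3,
    "Invertebrate": 3, "Jellyfish": 3, "Calamari": 3, "Mussel": 3,
    "Mantis": 3, "Sponge": 3, "Cockroach": 3, "Ladybug": 3, "Octopus": 3,

    "Fish(es)": 4, "Shark": 4, "Stingray": 4,

    "Frog": 5,

    "Snake": 6, "Crocodile": 6, "Lizard": 6, "Turtle": 6, "Reptile": 6,
    "Chameleon": 6, "Iguana": 6, "Dragon": 6,

    "Bird(s)": 7, "Eagle": 7, "Bat": 7, "Penguin": 7, "Parrot": 7,
    "Falcon": 7, "Pigeon": 7, "Duck": 7, "Cock, Rooster": 7,
    "Chicken, Chick": 7, "Owl": 7, "Partridge": 7, "Sparrow": 7,
    "Hawk": 7, "Canary": 7, "Ostrich": 7, "Vulture": 7,

    "Lion": 8, "Bear": 8, "Tiger": 8, "Monkey": 8, "Giraffe": 8,
    "Elephant": 8, "Whale": 8, "Wolf": 8, "Fox": 8, "Gorilla": 8,
    "Dolphin": 8, "Kangaroo": 8, "Koala": 8, "Hippopotamus": 8,
    "Zebra": 8, "Hedgehog": 8, "Animal(s)": 8, "Squirrel": 8, "Panda": 8,
    "Monk seal": 8, "Leopard": 8, "Weasel": 8, "Panther": 8,
    "Vertebrate": 8, "Tapir": 8, "Gazelle": 8, "Cougar": 8, "Skunk": 8,
    "Cheetah": 8, "Rhinoceros": 8, "Otter": 8, "Anteater": 8, "Hyena": 8,
    "Pork": 8, "Lynx": 8,

    "Dog": 9, "Cat": 9, "Mouse": 9, "Rabbit": 9, "Cow": 9, "Horse": 9,
    "Donkey": 9, "Sheep": 9, "Ox": 9, "Camel": 9, "Goat": 9,
    "Mammal(s)": 9, "Calf": 9, "Lamb": 9, "Buffalo": 9, "Lama": 9,
    "Mule": 9, "Bull": 9,

    "Human": 10
  },
  "person_names": [
    "Ali", "Ayse", "Mehmet", "Fatma", "Zeynep", "Ahmet", "Emine",
    "Mustafa", "Hatice", "Huseyin", "Elif", "Ibrahim", "Meryem", "Hasan"
  ]
}
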